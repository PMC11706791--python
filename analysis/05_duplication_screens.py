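"""Both duplication screens on the synthetic data: the per-gene read-depth
IQR outlier screen scored against the generator's truth, and the NG86 Ks
plot of the paralog pairs with its recent-duplication window fractions.

Writes results/depth_outliers.tsv and results/ks_plot.tsv.
"""

import json
import math

from Bio import SeqIO

from _shared import RESULTS, ensure_data

from copegen.duplication_signals import depth_outliers, ks_histogram, ng86_ks


def main():
    data = ensure_data()
    truth = json.loads((data / "depth_truth.json").read_text())
    depths = {}
    for line in open(data / "depths.tsv"):
        g, d = line.split()
        depths[g] = float(d)
    recs = depth_outliers(depths, k=1.5)
    flagged = {r.gene_id for r in recs if r.outlier_high}
    dup = set(truth["duplicated"])
    with open(RESULTS / "depth_outliers.tsv", "w") as fh:
        fh.write("gene_id\tdepth\toutlier_high\ttruly_duplicated\n")
        for r in recs:
            fh.write(f"{r.gene_id}\t{r.depth:.0f}\t{int(r.outlier_high)}"
                     f"\t{int(r.gene_id in dup)}\n")
    sens = len(flagged & dup) / len(dup)
    fdr = len(flagged - dup) / max(1, len(flagged))
    print(f"depth screen: {len(flagged)}/{len(depths)} genes flagged "
          f"({100 * len(flagged) / len(depths):.1f}%), sensitivity "
          f"{sens:.2f}, FDR {fdr:.3f}")

    seqs = {r.id: str(r.seq)
            for r in SeqIO.parse(str(data / "pairs.fasta"), "fasta")}
    pairs = [ng86_ks(seqs[p + "_a"], seqs[p + "_b"], p + "_a", p + "_b")
             for p in sorted({i[:-2] for i in seqs})]
    hist = ks_histogram(pairs)
    with open(RESULTS / "ks_plot.tsv", "w") as fh:
        fh.write("id_a\tks\n")
        for p in pairs:
            fh.write(f"{p.id_a}\t{p.ks:.5f}\n")
    finite = [p.ks for p in pairs if math.isfinite(p.ks)]
    print(f"Ks plot: {len(finite)} pairs, mean Ks {sum(finite)/len(finite):.3f}")
    for (lo, hi), frac in hist["window_fractions"].items():
        print(f"  fraction of pairs with Ks in [{lo:g}, {hi:g}]: {frac:.2f}")


if __name__ == "__main__":
    main()
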