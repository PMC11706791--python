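"""Per-gene CpG_o/e landscape: distribution summary, depletion percentage,
and the 5% tail sets used downstream for enrichment and as the
housekeeping-like reference.

Writes results/cpg_oe.tsv and the tail gene lists.
"""

from _shared import RESULTS, ensure_data

from copegen.cpg_metrics import compute_cpg_oe, summarize, tail_sets
from copegen.genome_io import extract_cds, load_genome


def main():
    data = ensure_data()
    bundle = load_genome(data / "genome.fasta", data / "genes.gff3",
                         data / "labels.tsv")
    records = [compute_cpg_oe(extract_cds(bundle, g.gene_id), g.gene_id)
               for g in bundle.genes if g.has_cds]
    s = summarize(records, threshold=1.0)
    low, high = tail_sets(records, q=0.05)

    with open(RESULTS / "cpg_oe.tsv", "w") as fh:
        fh.write("gene_id\tL\tn_CpG\tcpg_oe\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.L}\t{r.n_CpG}\t{r.cpg_oe:.4f}\n")
    (RESULTS / "cpg_low_tail.txt").write_text(
        "".join(r.gene_id + "\n" for r in low))
    (RESULTS / "cpg_high_tail.txt").write_text(
        "".join(r.gene_id + "\n" for r in high))

    ion = [r.cpg_oe for r in records
           if "ion_transport" in bundle.gene(r.gene_id).labels]
    print(f"{s.n_genes} genes: mean CpG_o/e = {s.mean:.3f} (sd {s.sd:.3f}), "
          f"{s.percent_below}% below 1 ({s.n_modes} density mode(s))")
    print(f"ion-transport subset mean CpG_o/e = "
          f"{sum(ion) / len(ion):.3f} ({len(ion)} genes)")
    print(f"5% tails: {len(low)} genes each; tables in {RESULTS}")


if __name__ == "__main__":
    main()
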