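"""Chromosomal clustering of the ion-transport gene set: adjacent-spacing
distributions, KS tests under all three null conventions, the chi-square
comparison against an equal-sized high-CpG_o/e (housekeeping-like)
reference set, per-chromosome counts, and centromere-proximal tallies.

Writes results/clustering.json and results/spacings.tsv.
"""

import json

import numpy as np

from _shared import RESULTS, SEED, ensure_data

from copegen.cpg_metrics import compute_cpg_oe
from copegen.genome_io import extract_cds, load_genome
from copegen.pipeline import _read_centromeres
from copegen.spatial_clustering import (
    SpacingSet,
    centromere_proximity,
    chisq_vs_reference,
    ks_clustering_test,
    per_chromosome_counts,
    spacings,
)


def main():
    data = ensure_data()
    bundle = load_genome(data / "genome.fasta", data / "genes.gff3",
                         data / "labels.tsv",
                         _read_centromeres(data / "centromeres.tsv"))
    sset = spacings(bundle, "ion_transport")
    out = {"n_genes": sset.n_genes,
           "per_chromosome": per_chromosome_counts(bundle, "ion_transport")}
    for mode in ("uniform-spacing", "position-uniform", "montecarlo"):
        r = ks_clustering_test(sset, mode, rng_seed=SEED)
        out[mode] = {"D": round(r.D, 4), "p": r.p_value, "n": r.n}
        print(f"KS [{mode:17s}]: D = {r.D:.3f}, p = {r.p_value:.3g}")

    # reference: equal count of the highest-CpG_o/e genes
    records = [compute_cpg_oe(extract_cds(bundle, g.gene_id), g.gene_id)
               for g in bundle.genes if g.has_cds]
    ranked = sorted((r for r in records if r.defined),
                    key=lambda r: (-r.cpg_oe, r.gene_id))
    ref_ids = {r.gene_id for r in ranked[:sset.n_genes]}
    ref_genes = [g for g in bundle.genes if g.gene_id in ref_ids]
    per = {}
    for chrom in sorted({g.chrom for g in ref_genes}):
        mids = np.sort([g.midpoint for g in ref_genes if g.chrom == chrom])
        per[chrom] = (bundle.chrom_map[chrom].length, mids)
    chi = chisq_vs_reference(sset, SpacingSet(per))
    out["chisq_vs_high_cpg"] = {"chi2": round(chi.chi2, 2), "df": chi.df,
                                "p": chi.p_value}
    print(f"chi-square vs high-CpG reference: chi2 = {chi.chi2:.1f}, "
          f"df = {chi.df}, p = {chi.p_value:.3g}")

    prox = centromere_proximity(bundle, "ion_transport", window_bp=100_000)
    out["centromere_proximal_100kb"] = prox
    print("ion-transport genes within 100 kb of the centromere:", prox)

    with open(RESULTS / "spacings.tsv", "w") as fh:
        fh.write("spacing_bp\n")
        fh.writelines(f"{s:.0f}\n" for s in sset.pooled)
    (RESULTS / "clustering.json").write_text(json.dumps(out, indent=1))


if __name__ == "__main__":
    main()
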