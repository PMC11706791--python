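"""Term enrichment of the low-CpG_o/e tail: because the generator gives
ion-transport genes deeper CpG depletion, their functional tag should be
over-represented among the 5% lowest-CpG_o/e genes.

Writes results/enrichment.tsv.
"""

from _shared import RESULTS, ensure_data

from copegen.cpg_metrics import compute_cpg_oe, tail_sets
from copegen.genome_io import extract_cds, load_genome
from copegen.term_enrichment import enrich, share_matching


def main():
    data = ensure_data()
    bundle = load_genome(data / "genome.fasta", data / "genes.gff3",
                         data / "labels.tsv")
    records = [compute_cpg_oe(extract_cds(bundle, g.gene_id), g.gene_id)
               for g in bundle.genes if g.has_cds]
    low, _high = tail_sets(records, q=0.05)
    study = {r.gene_id for r in low}
    population = {r.gene_id for r in records if r.defined}
    # functional labels double as flat annotation terms
    term_map = {g.gene_id: set(g.labels) for g in bundle.genes}

    results = enrich(study, population, term_map)
    with open(RESULTS / "enrichment.tsv", "w") as fh:
        fh.write("term_id\tk\tn\tK\tN\tp_value\tq_value\n")
        for r in results:
            fh.write(f"{r.term_id}\t{r.k}\t{r.n}\t{r.K}\t{r.N}"
                     f"\t{r.p_value:.3g}\t{r.q_value:.3g}\n")

    for r in results:
        flag = "*" if r.q_value < 0.05 else " "
        print(f"{flag} {r.term_id}: {r.k}/{r.n} study vs {r.K}/{r.N} "
              f"population, p={r.p_value:.2e}, q={r.q_value:.2e}")
    sig = [r.term_id for r in results if r.q_value < 0.05]
    if sig:
        m, t, pct = share_matching(sig, ["ion"])
        print(f"ion-related terms among significant: {m}/{t} = {pct}%")


if __name__ == "__main__":
    main()
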