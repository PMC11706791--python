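"""k-mer genome-size estimation from the simulated reads: canonical 21-mer
histogram, error cutoff, coverage peak, and the size estimate compared to
the known genome length.

Writes results/kmer_histogram.tsv and results/genome_size.json.
"""

import json

from _shared import RESULTS, ensure_data

from copegen.kmer_size import count_kmers, estimate_genome_size


def main():
    data = ensure_data()
    hist = count_kmers(data / "reads.fastq", k=21)
    est = estimate_genome_size(hist)
    true_size = len(
        (data / "size_region.fasta").read_text().splitlines()[1]
    )
    with open(RESULTS / "kmer_histogram.tsv", "w") as fh:
        fh.write("multiplicity\tn_distinct_kmers\n")
        for m in sorted(hist.counts):
            fh.write(f"{m}\t{hist.counts[m]}\n")
    rel = est["est_size"] / true_size - 1
    print(f"k=21 histogram: {hist.n_distinct:,} distinct canonical k-mers, "
          f"{hist.total_kmers:,} instances")
    print(f"error cutoff {est['error_cutoff']}, coverage peak {est['peak']} "
          f"(mean {est['mean_coverage']:.2f})")
    print(f"estimated genome size {est['est_size']:,.0f} bp vs true "
          f"{true_size:,} bp ({rel:+.2%})")
    (RESULTS / "genome_size.json").write_text(json.dumps({
        "est_size_bp": est["est_size"], "true_size_bp": true_size,
        "error_cutoff": est["error_cutoff"], "peak": est["peak"],
        "mean_coverage": est["mean_coverage"],
    }, indent=1))


if __name__ == "__main__":
    main()
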