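"""k-mer histogram and coverage-peak genome-size estimation.

With reads at coverage c and read length r, every position of a genome of
size G is covered by about lambda = c*(r-k+1)/r copies of each k-mer, so the
multiplicity histogram of distinct k-mers peaks at lambda.  Dividing the
total number of k-mer instances above the error cutoff by that modal
multiplicity recovers G.  This is the classic peak estimator — a deliberate
simplification of mixture-model tools, adequate for homozygous/inbred
genomes and used here at desk scale with plain in-memory hash counting.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import SeqIO

__all__ = ["KmerHistogram", "count_kmers", "estimate_genome_size"]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _canonical(kmer: str) -> str:
    rc = kmer.translate(_COMPLEMENT)[::-1]
    return kmer if kmer <= rc else rc


@dataclass
class KmerHistogram:
    """Multiplicity histogram of canonical k-mers.

    ``counts[m]`` = number of distinct canonical k-mers seen exactly m
    times; ``total_kmers`` = sum of m*counts[m] = number of valid k-mer
    windows counted.
    """

    k: int
    counts: dict[int, int]

    @property
    def total_kmers(self) -> int:
        return sum(m * c for m, c in self.counts.items())

    @property
    def n_distinct(self) -> int:
        return sum(self.counts.values())


def _iter_reads(reads):
    if isinstance(reads, (str, Path)):
        path = Path(reads)
        fmt = "fastq" if path.suffix in (".fq", ".fastq") else "fasta"
        for rec in SeqIO.parse(str(path), fmt):
            yield str(rec.seq).upper()
    else:
        for r in reads:
            yield str(r).upper()

def count_kmers(reads, k: int) -> KmerHistogram:
    """Count canonical k-mers (lexicographic min of k-mer and its reverse
    complement) over reads given as a FASTA/FASTQ path or an iterable of
    sequences.  Windows containing N (or any non-ACGT) are skipped; k must
    be odd so no k-mer is its own reverse complement."""
    if k % 2 == 0:
        raise ValueError("k must be odd (even k makes canonicalization ambiguous)")
    if k < 1:
        raise ValueError("k must be positive")
    table: dict[str, int] = {}
    acgt = set("ACGT")
    for seq in _iter_reads(reads):
        L = len(seq)
        if L < k:
            continue
        bad = [i for i, c in enumerate(seq) if c not in acgt]
        if bad:
            valid = np.ones(L - k + 1, dtype=bool)
            for b in bad:
                valid[max(0, b - k + 1) : b + 1] = False
            starts = np.flatnonzero(valid)
        else:
            starts = range(L - k + 1)
        rc = seq.translate(_COMPLEMENT)[::-1]
        for i in starts:
            kmer = seq[i : i + k]
            kmer_rc = rc[L - i - k : L - i]
            if kmer_rc < kmer:
                kmer = kmer_rc
            table[kmer] = table.get(kmer, 0) + 1
    counts: dict[int, int] = {}
    for m in table.values():
        counts[m] = counts.get(m, 0) + 1
    return KmerHistogram(k=k, counts=counts)


def _smooth(values: np.ndarray) -> np.ndarray:
    """3-point moving average with edge replication."""
    padded = np.concatenate([values[:1], values, values[-1:]])
    return (padded[:-2] + padded[1:-1] + padded[2:]) / 3


def estimate_genome_size(histogram: KmerHistogram) -> dict:
    """Coverage-peak genome-size estimate from a k-mer histogram.

    The error cutoff is the first local minimum of the 3-point-smoothed
    histogram (multiplicity 1 when the histogram rises from the start,
    i.e. no error k-mers); the peak is the modal multiplicity above the
    cutoff.  The estimate divides sum_{m >= cutoff} m*count(m) by the mean
    coverage of the single-copy component, measured as the count-weighted
    mean multiplicity within peak +/- 3*sqrt(peak): the raw integer mode is
    too granular (a one-unit flip moves the estimate by ~1/peak), while the
    windowed mean tracks the true per-k-mer coverage to a few tenths of a
    percent and still excludes error k-mers below and repeat k-mers above.
    """
    if not histogram.counts:
        raise ValueError("empty histogram")
    max_m = max(histogram.counts)
    dense = np.zeros(max_m + 1)
    for m, c in histogram.counts.items():
        dense[m] = c
    smooth = _smooth(dense[1:])  # index 0 of smooth = multiplicity 1

    cutoff = 1
    if len(smooth) >= 2 and smooth[0] > smooth[1]:
        # error peak present: walk down to the first local minimum
        i = 1
        while i + 1 < len(smooth) and smooth[i + 1] <= smooth[i]:
            i += 1
        if i + 1 >= len(smooth):
            raise ValueError(
                "monotone k-mer histogram: no error/coverage separation — "
                "increase coverage"
            )
        cutoff = i + 1  # multiplicity of the local minimum

    above = dense[cutoff:]
    if above.sum() == 0 or np.argmax(above) == 0 and cutoff > 1:
        raise ValueError("no coverage peak above the error cutoff")
    peak = cutoff + int(np.argmax(above))
    if peak <= cutoff and cutoff > 1:
        raise ValueError("coverage peak not separated from error k-mers")
    total = sum(m * c for m, c in histogram.counts.items() if m >= cutoff)
    half_width = 3 * math.sqrt(peak)
    lo = max(cutoff, math.ceil(peak - half_width))
    hi = math.floor(peak + half_width)
    window = [(m, c) for m, c in histogram.counts.items() if lo <= m <= hi]
    coverage = sum(m * c for m, c in window) / sum(c for _, c in window)
    return {
        "k": histogram.k,
        "error_cutoff": cutoff,
        "peak": peak,
        "mean_coverage": coverage,
        "est_size": total / coverage,
        "total_kmers_used": total,
    }
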