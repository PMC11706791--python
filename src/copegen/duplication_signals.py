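"""Gene-duplication screens: read-depth IQR outliers and NG86 Ks dating.

Two independent lines of evidence for duplicated genes: (1) genes whose
mapped-read depth far exceeds the cohort's central tendency collapse reads
from several near-identical copies onto one model, so an upper IQR fence
flags putative duplicates; (2) synonymous divergence (Ks) between paralog
pairs dates duplication events — an excess of pairs at very low Ks means
recent duplication, and the shape of the Ks histogram distinguishes
continuous duplication from a whole-genome-duplication burst.

Ks here is Nei–Gojobori (1986) counting with Jukes–Cantor correction:
per-codon synonymous site fractions from the universal code, multi-hit
codons averaged over all minimal mutational pathways, and
Ks = -(3/4) ln(1 - (4/3) ps).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations

import numpy as np

__all__ = [
    "DepthRecord",
    "KsPair",
    "depth_outliers",
    "ng86_ks",
    "ks_histogram",
    "mean_depth_from_bed",
]

# universal genetic code over DNA codons
_BASES = "ACGT"
_CODON_TABLE: dict[str, str] = {}


def _build_code() -> None:
    from Bio.Data.CodonTable import standard_dna_table

    _CODON_TABLE.update(standard_dna_table.forward_table)
    for stop in standard_dna_table.stop_codons:
        _CODON_TABLE[stop] = "*"


_build_code()


@dataclass(frozen=True)
class DepthRecord:
    gene_id: str
    depth: float
    q1: float
    q3: float
    iqr: float
    outlier_high: bool
    low_side: bool


def depth_outliers(
    depth_table: dict[str, float], k: float = 1.5
) -> list[DepthRecord]:
    """Flag genes whose read depth exceeds Q3 + k*IQR of the cohort.

    Quartiles by linear interpolation (type 7).  High-side exceedances are
    the duplication candidates (``outlier_high``); low-side deviations
    below Q1 - k*IQR are flagged separately (``low_side``) as possible
    annotation artifacts but are not counted as duplication outliers.
    """
    if len(depth_table) < 4:
        raise ValueError("need at least 4 genes for quartile screening")
    depths = np.array(list(depth_table.values()), dtype=float)
    if (depths < 0).any():
        raise ValueError("negative depths are invalid")
    q1, q3 = np.quantile(depths, [0.25, 0.75])  # linear interpolation
    iqr = q3 - q1
    hi, lo = q3 + k * iqr, q1 - k * iqr
    return [
        DepthRecord(
            gene_id=g,
            depth=d,
            q1=float(q1),
            q3=float(q3),
            iqr=float(iqr),
            outlier_high=bool(d > hi),
            low_side=bool(d < lo),
        )
        for g, d in depth_table.items()
    ]


def mean_depth_from_bed(
    per_base_bed: str, genes: dict[str, tuple[str, int, int]]
) -> dict[str, float]:
    """Aggregate a per-base depth BED (chrom, start, end, depth; 0-based
    half-open runs) into mean depth over each gene span."""
    runs: dict[str, list[tuple[int, int, float]]] = {}
    with open(per_base_bed) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, s, e, d = line.split()[:4]
            runs.setdefault(chrom, []).append((int(s), int(e), float(d)))
    out = {}
    for gene_id, (chrom, gs, ge) in genes.items():
        total = 0.0
        for s, e, d in runs.get(chrom, ()):
            ov = min(e, ge) - max(s, gs)
            if ov > 0:
                total += ov * d
        out[gene_id] = total / (ge - gs)
    return out


# ---------------------------------------------------------------- NG86 ----


@dataclass(frozen=True)
class KsPair:
    id_a: str
    id_b: str
    S: float  # synonymous sites (pair average)
    N: float  # nonsynonymous sites
    sd: float  # synonymous differences, pathway-averaged
    nd: float  # nonsynonymous differences
    ps: float  # sd / S
    pn: float  # nd / N
    ks: float  # JC-corrected; inf when ps >= 3/4
    ka: float


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site count of one codon: at each
    position, the fraction of the three single-nucleotide changes that
    preserve the amino acid.  Changes to stop codons are nonsynonymous."""
    aa = _CODON_TABLE[codon]
    s = 0.0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            neighbor = codon[:pos] + alt + codon[pos + 1 :]
            if _CODON_TABLE[neighbor] != "*" and _CODON_TABLE[neighbor] == aa:
                s += 1 / 3
    return s, 3.0 - s


def _codon_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over all minimal mutational pathways (orderings of the differing
    positions); a step that changes the encoded amino acid (or hits a stop)
    counts as nonsynonymous."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    sd = nd = 0.0
    paths = list(permutations(diff_pos))
    w = 1.0 / len(paths)
    for path in paths:
        cur = c1
        for pos in path:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if _CODON_TABLE[cur] == _CODON_TABLE[nxt] and _CODON_TABLE[cur] != "*":
                sd += w
            else:
                nd += w
            cur = nxt
    return sd, nd


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.inf
    if p <= 0:
        return 0.0
    return -0.75 * math.log(1 - (4 / 3) * p)


def ng86_ks(cds_a: str, cds_b: str, id_a: str = "a", id_b: str = "b") -> KsPair:
    """NG86 synonymous/nonsynonymous divergence of an in-frame codon
    alignment (equal lengths, multiple of 3, no internal stops)."""
    if len(cds_a) != len(cds_b):
        raise ValueError(f"length mismatch: {len(cds_a)} vs {len(cds_b)}")
    if len(cds_a) % 3 != 0 or len(cds_a) == 0:
        raise ValueError("sequence length must be a positive multiple of 3")
    codons_a = [cds_a[i : i + 3] for i in range(0, len(cds_a), 3)]
    codons_b = [cds_b[i : i + 3] for i in range(0, len(cds_b), 3)]
    for c in codons_a + codons_b:
        if c not in _CODON_TABLE:
            raise ValueError(f"invalid codon {c!r}")
        if _CODON_TABLE[c] == "*":
            raise ValueError(f"internal stop codon {c!r}")
    s_a = sum(_codon_sites(c)[0] for c in codons_a)
    s_b = sum(_codon_sites(c)[0] for c in codons_b)
    S = (s_a + s_b) / 2
    N = len(cds_a) - S
    sd = nd = 0.0
    for ca, cb in zip(codons_a, codons_b):
        ds, dn = _codon_diffs(ca, cb)
        sd += ds
        nd += dn
    ps = sd / S if S > 0 else 0.0
    pn = nd / N if N > 0 else 0.0
    return KsPair(
        id_a=id_a, id_b=id_b, S=S, N=N, sd=sd, nd=nd, ps=ps, pn=pn,
        ks=_jukes_cantor(ps), ka=_jukes_cantor(pn),
    )


def ks_histogram(
    pairs: list[KsPair],
    bin_width: float = 0.01,
    windows: tuple[tuple[float, float], ...] = ((0.0, 0.04), (0.00002, 0.09)),
) -> dict:
    """Ks-plot histogram plus the fraction of pairs in each age window.

    Windows are inclusive on both ends (a pair at exactly Ks=0 falls in a
    window starting at 0).  Infinite-Ks (saturated) pairs are excluded from
    the histogram and window fractions but reported in ``n_saturated``.
    """
    finite = np.array([p.ks for p in pairs if math.isfinite(p.ks)])
    n_sat = sum(1 for p in pairs if not math.isfinite(p.ks))
    if finite.size == 0:
        raise ValueError("no finite Ks values")
    n_bins = max(1, math.ceil((finite.max() + 1e-12) / bin_width))
    edges = np.arange(0, (n_bins + 1)) * bin_width
    counts, _ = np.histogram(finite, bins=edges)
    window_fractions = {
        w: float(((finite >= w[0]) & (finite <= w[1])).mean()) for w in windows
    }
    return {
        "bin_edges": edges,
        "counts": counts,
        "n_pairs": int(finite.size),
        "n_saturated": n_sat,
        "window_fractions": window_fractions,
    }
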