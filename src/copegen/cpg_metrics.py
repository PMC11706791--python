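"""Per-gene CpG observed/expected ratios and genome-wide summaries.

CpG_o/e = f_CpG / (f_C * f_G) over a gene's coding sequence, with
f_C = n_C/L, f_G = n_G/L and f_CpG = n_CpG/(L-1) (overlapping dinucleotide
windows).  Depressed values are the classic footprint of historical
gene-body cytosine methylation: deamination of 5-methylcytosine erodes CpG
dinucleotides over evolutionary time, so a heavily methylated gene body
drifts toward CpG_o/e well below 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy.stats import gaussian_kde

logger = logging.getLogger(__name__)

__all__ = [
    "CpGRecord",
    "CpGSummary",
    "compute_cpg_oe",
    "summarize",
    "tail_sets",
    "round_percent",
]


def round_percent(count: int, total: int, decimals: int = 1) -> float:
    """Percentage rounded half away from zero (66.25 -> 66.3, not 66.2)."""
    if total == 0:
        raise ValueError("total must be > 0")
    pct = Decimal(int(count)) * 100 / Decimal(int(total))
    q = Decimal(10) ** -decimals
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CpGRecord:
    """Nucleotide/dinucleotide counts and the CpG_o/e ratio for one gene.

    ``L`` counts only unambiguous ACGT positions; windows touching a
    non-ACGT base are excluded from both numerator and denominator, with
    ``n_windows`` adjusted accordingly (``n_windows = L - 1`` for a clean
    sequence).  ``defined`` is False when f_C*f_G == 0.
    """

    gene_id: str
    L: int
    n_windows: int
    n_C: int
    n_G: int
    n_CpG: int
    f_C: float
    f_G: float
    f_CpG: float
    cpg_oe: float
    defined: bool


def compute_cpg_oe(seq: str, gene_id: str = "") -> CpGRecord:
    """CpG_o/e of one coding sequence (uppercase; non-ACGT excluded)."""
    if len(seq) < 2:
        raise ValueError("sequence shorter than 2 nt")
    valid = [c in "ACGT" for c in seq]
    L = sum(valid)
    n_C = sum(1 for c, v in zip(seq, valid) if v and c == "C")
    n_G = sum(1 for c, v in zip(seq, valid) if v and c == "G")
    n_windows = sum(1 for i in range(len(seq) - 1) if valid[i] and valid[i + 1])
    n_CpG = sum(
        1 for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"
    )
    if L < 2 or n_windows == 0:
        raise ValueError("fewer than 2 unambiguous positions")
    f_C = n_C / L
    f_G = n_G / L
    f_CpG = n_CpG / n_windows
    if f_C * f_G == 0:
        logger.warning(
            "gene %s: f_C*f_G = 0, CpG_o/e undefined; excluded from summaries",
            gene_id or "<anonymous>",
        )
        return CpGRecord(gene_id, L, n_windows, n_C, n_G, n_CpG, f_C, f_G, f_CpG,
                         math.nan, False)
    return CpGRecord(
        gene_id, L, n_windows, n_C, n_G, n_CpG, f_C, f_G, f_CpG,
        f_CpG / (f_C * f_G), True,
    )


@dataclass(frozen=True)
class CpGSummary:
    """Genome-wide CpG_o/e distribution summary over defined records."""

    n_genes: int
    n_undefined: int
    mean: float
    sd: float
    min: float
    max: float
    threshold: float
    n_below: int
    fraction_below: float
    percent_below: float
    n_modes: int


def _kde_mode_count(values: np.ndarray) -> int:
    """Descriptive mode count of the CpG_o/e density (Scott's-rule KDE
    evaluated on a fixed grid); no formal dip test is attempted."""
    if len(values) < 10 or np.ptp(values) == 0:
        return 1
    kde = gaussian_kde(values)
    grid = np.linspace(values.min(), values.max(), 512)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    return max(1, int(interior.sum()))


def summarize(records: list[CpGRecord], threshold: float = 1.0) -> CpGSummary:
    """Mean/sd/min/max and fraction below ``threshold``, defined records only."""
    vals = np.array([r.cpg_oe for r in records if r.defined])
    n_undef = sum(1 for r in records if not r.defined)
    if vals.size == 0:
        raise ValueError("all records undefined: no CpG_o/e values to summarize")
    n_below = int((vals < threshold).sum())
    return CpGSummary(
        n_genes=int(vals.size),
        n_undefined=n_undef,
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        min=float(vals.min()),
        max=float(vals.max()),
        threshold=threshold,
        n_below=n_below,
        fraction_below=n_below / vals.size,
        percent_below=round_percent(n_below, int(vals.size)),
        n_modes=_kde_mode_count(vals),
    )


def tail_sets(
    records: list[CpGRecord], q: float = 0.05
) -> tuple[list[CpGRecord], list[CpGRecord]]:
    """The floor(q*n) lowest- and highest-CpG_o/e genes (defined records).

    Ties are broken by gene_id so the sets are deterministic.  Used for the
    bottom/top-5% enrichment contrasts and as the "functionally conserved"
    (high-CpG_o/e housekeeping-like) reference pool.
    """
    if not (0 < q < 0.5):
        raise ValueError("q must be in (0, 0.5)")
    defined = [r for r in records if r.defined]
    k = math.floor(q * len(defined))
    if k == 0:
        raise ValueError(f"floor(q*n) = 0 for q={q}, n={len(defined)}")
    ordered = sorted(defined, key=lambda r: (r.cpg_oe, r.gene_id))
    return ordered[:k], ordered[-k:]
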