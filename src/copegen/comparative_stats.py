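"""Order-level comparative statistics and small population-genetic calculators.

Karyotype and genome-size comparisons across copepod orders are rank-based:
a tie-corrected Kruskal–Wallis test across groups, pairwise rank-sum
(Mann–Whitney) tests with BH adjustment, and group medians.  The module
also carries the Pearson correlation used for genome size vs repeat
content, and the Ne = theta_W / (4 mu) calculator.

Note on terminology: group comparisons here are between independent sets of
species, so the pairwise test is the rank-sum (Mann–Whitney) test; the
signed-rank variant applies only to paired samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TraitTable",
    "RankTestResult",
    "PopGenParams",
    "kruskal_wallis",
    "pairwise_wilcoxon",
    "group_medians",
    "pearson_r",
    "effective_pop_size",
]


@dataclass
class TraitTable:
    """Rows of (species, group, value): one trait value per species, grouped
    by taxonomic order.  Values are taken as tabulated (e.g. haploid or
    diploid chromosome counts, genome sizes in Mb)."""

    df: pd.DataFrame

    @classmethod
    def from_tsv(cls, path: str) -> "TraitTable":
        df = pd.read_csv(path, sep="\t")
        return cls(df[["species", "group", "value"]])

    @classmethod
    def from_records(cls, rows: list[tuple[str, str, float]]) -> "TraitTable":
        return cls(pd.DataFrame(rows, columns=["species", "group", "value"]))

    def __post_init__(self) -> None:
        if (self.df["value"] <= 0).any():
            raise ValueError("trait values must be positive")

    def groups(self) -> dict[str, np.ndarray]:
        return {
            g: sub["value"].to_numpy(float)
            for g, sub in self.df.groupby("group", sort=True)
        }


@dataclass(frozen=True)
class RankTestResult:
    H: float
    df: int
    p_value: float


def kruskal_wallis(table: TraitTable) -> RankTestResult:
    """Tie-corrected Kruskal–Wallis H across groups, chi-square p-value."""
    groups = list(table.groups().values())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    df = len(groups) - 1
    values = np.concatenate(groups)
    if np.ptp(values) == 0:
        return RankTestResult(H=0.0, df=df, p_value=1.0)
    H, p = stats.kruskal(*groups)
    return RankTestResult(H=float(H), df=df, p_value=float(p))


def pairwise_wilcoxon(table: TraitTable, adjust: str = "fdr_bh") -> pd.DataFrame:
    """Pairwise two-sided rank-sum tests between all group pairs.

    Tie-free pairs with <= 25 values per group use the exact null
    distribution; larger or tied pairs use the normal approximation with
    tie and continuity correction.  p-values are BH-adjusted across the
    pairs.  Returns a symmetric matrix with 1.0 on the diagonal.
    """
    groups = table.groups()
    names = sorted(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    pairs = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    raw = []
    for a, b in pairs:
        x, y = groups[a], groups[b]
        tie_free = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
        method = "exact" if tie_free and max(len(x), len(y)) <= 25 else "asymptotic"
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided", method=method, use_continuity=True,
        )
        raw.append(min(1.0, float(res.pvalue)))
    adj = multipletests(raw, method=adjust)[1] if pairs else []
    mat = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for (a, b), q in zip(pairs, adj):
        mat.loc[a, b] = mat.loc[b, a] = float(q)
    np.fill_diagonal(mat.values, 1.0)
    return mat


def group_medians(table: TraitTable) -> dict[str, float]:
    """Median trait value per group (even counts: mean of the central pair)."""
    return {g: float(np.median(v)) for g, v in table.groups().items()}


def pearson_r(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need n >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y")
    return float(stats.pearsonr(x, y).statistic)


@dataclass(frozen=True)
class PopGenParams:
    theta_w: float
    mu: float
    ne: float
    ne_order_of_magnitude: float


def effective_pop_size(theta_w: float, mu: float) -> PopGenParams:
    """Effective population size under neutrality: Ne = theta_W / (4 mu).

    Reports the exact value and its order-of-magnitude rounding
    (10^round(log10 Ne)), the scale at which such estimates are quoted.
    """
    if theta_w <= 0 or mu <= 0:
        raise ValueError("theta_w and mu must be positive")
    ne = theta_w / (4 * mu)
    return PopGenParams(
        theta_w=theta_w,
        mu=mu,
        ne=ne,
        ne_order_of_magnitude=10.0 ** round(math.log10(ne)),
    )
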