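"""Flat hypergeometric term enrichment with BH correction.

A deliberately database-free engine: terms are opaque identifiers supplied
as a gene -> terms map, so the same code serves GO-style annotations, custom
functional tags, or simulation truth labels.  Only over-representation
(upper tail) is tested, and no ontology-graph propagation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .cpg_metrics import round_percent

__all__ = ["EnrichmentResult", "enrich", "share_matching"]


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    k: int  # study genes carrying the term
    n: int  # study size
    K: int  # population genes carrying the term
    N: int  # population size
    p_value: float
    q_value: float


def enrich(
    study_genes: set[str] | list[str],
    population_genes: set[str] | list[str],
    term_map: dict[str, set[str]],
    method: str = "fdr_bh",
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric test per term, multiplicity-adjusted.

    p = P(X >= k) for X ~ Hypergeom(N, K, n); only terms with at least one
    study hit are tested and reported.  Adjustment is Benjamini–Hochberg by
    default (``method="bonferroni"`` for the conservative alternative).
    """
    study = set(study_genes)
    population = set(population_genes)
    stray = study - population
    if stray:
        raise ValueError(f"study genes not in population: {sorted(stray)}")
    N = len(population)
    n = len(study)

    term_pop: dict[str, int] = {}
    term_study: dict[str, int] = {}
    for gene in population:
        for term in term_map.get(gene, ()):
            term_pop[term] = term_pop.get(term, 0) + 1
            if gene in study:
                term_study[term] = term_study.get(term, 0) + 1

    tested = sorted(term_study)
    pvals = [
        float(hypergeom.sf(term_study[t] - 1, N, term_pop[t], n)) for t in tested
    ]
    if not tested:
        return []
    _, qvals, _, _ = multipletests(pvals, method=method)
    results = [
        EnrichmentResult(
            term_id=t,
            k=term_study[t],
            n=n,
            K=term_pop[t],
            N=N,
            p_value=p,
            q_value=float(q),
        )
        for t, p, q in zip(tested, pvals, qvals)
    ]
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def share_matching(
    terms: list[str], pattern_set: list[str]
) -> tuple[int, int, float]:
    """(matching_count, total, percent) of terms matching any pattern.

    A term matches when a pattern equals it or is a substring (keyword
    tagging, e.g. 'ion transport' against term descriptions).  Percent is
    rounded half away from zero to one decimal.
    """
    if not terms:
        raise ValueError("no terms to match against")
    matching = sum(
        1 for t in terms if any(p == t or p in t for p in pattern_set)
    )
    return matching, len(terms), round_percent(matching, len(terms))
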