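"""Spacing construction, KS clustering tests, chi-square comparison,
per-chromosome and centromere tallies."""

import numpy as np
import pytest
from scipy import stats

from copegen.genome_io import ChromosomeInfo, GeneModel, GenomeBundle
from copegen.spatial_clustering import (
    SpacingSet,
    centromere_proximity,
    chisq_vs_reference,
    ks_clustering_test,
    per_chromosome_counts,
    spacings,
)
from copegen.synthetic_data import PlacementSpec, place_genes


def _bundle_from_midpoints(mids_by_chrom, length=100_000, label="s",
                           centromeres=None):
    chroms, genes = [], []
    centromeres = centromeres or {}
    i = 0
    for chrom, mids in mids_by_chrom.items():
        chroms.append(ChromosomeInfo(chrom, length, centromeres.get(chrom)))
        for m in mids:
            genes.append(
                GeneModel(f"g{i:03d}", chrom, m - 5, m + 5, "+",
                          labels={label})
            )
            i += 1
    return GenomeBundle(chroms, genes, {c.name: "" for c in chroms})


def _spacing_set(values):
    """SpacingSet whose pooled spacings equal `values` (one chromosome)."""
    mids = np.concatenate([[0.0], np.cumsum(values)])
    return SpacingSet({"chr1": (int(mids[-1]) + 10, mids)})


class TestSpacings:
    def test_hand_example(self):
        b = _bundle_from_midpoints({"c1": [10, 20, 40]}, length=1000)
        assert list(spacings(b, "s").pooled) == [10, 20]

    def test_one_gene_per_chromosome_is_degenerate(self):
        b = _bundle_from_midpoints({f"c{i}": [50] for i in range(4)})
        with pytest.raises(ValueError):
            spacings(b, "s")

    def test_matches_sort_and_diff_oracle(self, rng):
        mids = {f"c{i}": sorted(rng.integers(10, 99_000, size=25).tolist())
                for i in range(4)}
        b = _bundle_from_midpoints(mids)
        got = sorted(spacings(b, "s").pooled)
        expected = sorted(
            d for v in mids.values() for d in np.diff(sorted(v))
        )
        assert got == pytest.approx(expected)

    def test_no_telomere_flank_distances(self):
        b = _bundle_from_midpoints({"c1": [10, 20]}, length=1000)
        assert spacings(b, "s").pooled.tolist() == [10]


class TestKsClusteringTest:
    def test_quantile_spacings_fit_uniform_null(self):
        n = 40
        sp = [1000 * i / (n + 1) for i in range(1, n + 1)]
        res = ks_clustering_test(_spacing_set(sp), "uniform-spacing")
        assert res.D <= 2 / n
        assert res.p_value > 0.9

    def test_d_equals_brute_force_sup(self, rng):
        """D from the implementation equals the exhaustive sup over ECDF
        step points against the Uniform(0, max) CDF, for random n <= 50."""
        for _ in range(25):
            n = int(rng.integers(5, 51))
            sp = rng.uniform(10, 5000, size=n)
            res = ks_clustering_test(_spacing_set(sp), "uniform-spacing")
            mx = sp.max()
            xs = np.sort(sp)
            cdf = xs / mx
            ecdf_hi = np.arange(1, n + 1) / n
            ecdf_lo = np.arange(0, n) / n
            brute = max(np.max(ecdf_hi - cdf), np.max(cdf - ecdf_lo))
            assert res.D == pytest.approx(brute, abs=1e-12)

    def test_too_few_spacings_advises_montecarlo(self):
        with pytest.raises(ValueError, match="montecarlo"):
            ks_clustering_test(_spacing_set([1, 2, 3]), "uniform-spacing")

    def test_position_uniform_mode_on_uniform_positions(self, rng):
        mids = np.sort(rng.uniform(0, 100_000, size=200))
        sset = SpacingSet({"c1": (100_000, mids)})
        res = ks_clustering_test(sset, "position-uniform")
        assert res.p_value > 0.01

    def test_montecarlo_detects_clusters_and_passes_uniform(self, rng):
        L = 1_000_000
        clustered = PlacementSpec("clustered", n_clusters=8,
                                  cluster_sd_bp=int(0.005 * L))
        per = {}
        for c in range(4):
            starts = place_genes(rng, L, 20, 1000, clustered)
            per[f"c{c}"] = (L, starts + 500)
        res = ks_clustering_test(SpacingSet(per), "montecarlo", rng_seed=5)
        assert res.p_value < 0.05
        per_u = {}
        for c in range(4):
            starts = place_genes(rng, L, 20, 1000, PlacementSpec("uniform"))
            per_u[f"c{c}"] = (L, starts + 500)
        res_u = ks_clustering_test(SpacingSet(per_u), "montecarlo", rng_seed=5)
        assert res_u.p_value > 0.05

    def test_montecarlo_p_is_seed_reproducible(self, rng):
        per = {"c1": (100_000, np.sort(rng.uniform(0, 100_000, 30)))}
        a = ks_clustering_test(SpacingSet(per), "montecarlo", rng_seed=9)
        b = ks_clustering_test(SpacingSet(per), "montecarlo", rng_seed=9)
        assert (a.D, a.p_value) == (b.D, b.p_value)


class TestChiSquare:
    def test_all_in_one_bin_hand_arithmetic(self):
        # 60 observations in 1 of 6 equal-mass bins:
        # (60-10)^2/10 + 5*(0-10)^2/10 = 300, df = 5
        ref = np.arange(1, 601, dtype=float)
        obs = np.full(60, 50.0)
        r = chisq_vs_reference(obs, ref, n_bins=6)
        assert r.chi2 == pytest.approx(300.0)
        assert r.df == 5
        assert r.observed.sum() == 60

    def test_default_bin_heuristic(self):
        ref = np.arange(1000, dtype=float)
        r490 = chisq_vs_reference(np.linspace(1, 999, 486), ref)
        assert r490.df == 15  # floor(486/30) = 16 bins
        r80 = chisq_vs_reference(np.linspace(1, 999, 76), ref)
        assert r80.df == 5  # max(6, floor(76/30)) = 6 bins

    def test_null_simulation_is_calibrated(self, rng):
        """Observed drawn from the reference distribution: median chi2
        is near df and p-values are roughly uniform (200 replicates)."""
        ref = rng.exponential(1000, size=5000)
        chis, ps = [], []
        for _ in range(200):
            obs = rng.choice(ref, size=480, replace=False)
            r = chisq_vs_reference(obs, ref, n_bins=16)
            chis.append(r.chi2)
            ps.append(r.p_value)
        assert np.median(chis) == pytest.approx(
            stats.chi2.median(15), rel=0.25
        )
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_underfilled_bins_are_rejected(self):
        ref = np.arange(100, dtype=float)
        with pytest.raises(ValueError, match="fewer bins"):
            chisq_vs_reference(np.arange(20, dtype=float), ref, n_bins=10)

    def test_small_reference_rejected(self):
        with pytest.raises(ValueError, match="reference"):
            chisq_vs_reference(np.arange(100.0), np.arange(50.0))


class TestCounts:
    def test_all_genes_on_one_chromosome(self):
        b = _bundle_from_midpoints({"c1": [10, 20, 30]})
        b.chromosomes.append(ChromosomeInfo("c2", 100_000))
        assert per_chromosome_counts(b, "s") == {"c1": 3, "c2": 0}

    def test_matches_groupby_oracle(self, small_bundle):
        counts = per_chromosome_counts(small_bundle, "ion_transport")
        oracle = {}
        for g in small_bundle.genes:
            if "ion_transport" in g.labels:
                oracle[g.chrom] = oracle.get(g.chrom, 0) + 1
        for chrom, n in oracle.items():
            assert counts[chrom] == n
        assert sum(counts.values()) == sum(oracle.values())


class TestCentromereProximity:
    def test_gene_at_centromere_counts_for_any_window(self):
        b = _bundle_from_midpoints({"c1": [500, 900]}, length=1000,
                                   centromeres={"c1": 500})
        assert centromere_proximity(b, "s", 0)["c1"] == 1
        assert centromere_proximity(b, "s", 1000)["c1"] == 2

    def test_missing_centromere_reports_none(self):
        b = _bundle_from_midpoints({"c1": [500, 900]}, length=1000)
        assert centromere_proximity(b, "s", 100)["c1"] is None

    def test_clustered_at_centromere_beats_uniform_null(self, rng):
        """Genes packed around the centromere exceed the 95th percentile
        of uniform-placement proximal counts (Monte-Carlo null)."""
        L, window, n = 1_000_000, 50_000, 30
        cent = L // 2
        mids = np.clip(rng.normal(cent, 20_000, size=n), 1, L - 1).astype(int)
        b = _bundle_from_midpoints({"c1": sorted(mids.tolist())}, length=L,
                                   centromeres={"c1": cent})
        observed = centromere_proximity(b, "s", window)["c1"]
        null = [
            int((np.abs(rng.uniform(0, L, size=n) - cent) <= window).sum())
            for _ in range(500)
        ]
        assert observed >= np.percentile(null, 95)
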