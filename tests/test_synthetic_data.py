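"""Generator determinism, truth files, and statistical closure."""

import hashlib
import json

import numpy as np
import pytest

from copegen.duplication_signals import depth_outliers
from copegen.synthetic_data import (
    BASE_COMPOSITION,
    DepthModel,
    ParalogModel,
    SyntheticGenomeSpec,
    gen_depths,
    gen_genome,
    gen_paralogs,
    gen_reads,
    gen_trait_table,
    markov_transition_matrix,
)


def _md5(path):
    return hashlib.md5(path.read_bytes()).hexdigest()


class TestMarkovModel:
    @pytest.mark.parametrize("w", [0.3, 1.0, 1.8])
    def test_rows_sum_to_one_and_stationary_is_composition(self, w):
        T = markov_transition_matrix(w)
        assert np.allclose(T.sum(axis=1), 1.0)
        p = np.array([BASE_COMPOSITION[b] for b in "ACGT"])
        assert np.allclose(p @ T, p)  # stationarity
        assert T.min() >= 0

    def test_cg_transition_scales_with_w(self):
        t1 = markov_transition_matrix(1.0)
        t2 = markov_transition_matrix(0.5)
        iC, iG = 1, 2
        assert t2[iC, iG] == pytest.approx(0.5 * t1[iC, iG])


class TestGenGenome:
    def test_seed_determinism(self, tmp_path):
        spec = SyntheticGenomeSpec(chrom_length=200_000, n_genes_per_chrom=10,
                                   rng_seed=5)
        gen_genome(spec, tmp_path / "a")
        gen_genome(spec, tmp_path / "b")
        for name in ("genome.fasta", "genes.gff3", "labels.tsv"):
            assert _md5(tmp_path / "a" / name) == _md5(tmp_path / "b" / name)

    def test_different_seed_differs(self, tmp_path):
        s1 = SyntheticGenomeSpec(chrom_length=200_000, n_genes_per_chrom=10,
                                 rng_seed=5)
        s2 = SyntheticGenomeSpec(chrom_length=200_000, n_genes_per_chrom=10,
                                 rng_seed=6)
        gen_genome(s1, tmp_path / "a")
        gen_genome(s2, tmp_path / "b")
        assert _md5(tmp_path / "a" / "genome.fasta") != _md5(
            tmp_path / "b" / "genome.fasta")

    def test_truth_json_is_self_sufficient(self, small_genome):
        outdir, truth = small_genome
        on_disk = json.loads((outdir / "truth.json").read_text())
        assert on_disk["genes"] == truth["genes"]
        assert on_disk["spec"]["cpg_odds"] == 0.5
        labels_file = {
            tuple(line.split("\t"))
            for line in (outdir / "labels.tsv").read_text().splitlines()
        }
        labels_truth = {
            (g["gene_id"], lab) for g in truth["genes"] for lab in g["labels"]
        }
        assert labels_file == labels_truth

    def test_infeasible_density_rejected(self):
        with pytest.raises(ValueError, match="density"):
            SyntheticGenomeSpec(chrom_length=100_000, n_genes_per_chrom=100,
                                cds_length=1500)

    def test_genes_do_not_overlap(self, small_genome):
        _, truth = small_genome
        by_chrom = {}
        for g in truth["genes"]:
            by_chrom.setdefault(g["chrom"], []).append((g["start"], g["end"]))
        for spans in by_chrom.values():
            spans.sort()
            for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
                assert s2 >= e1

    def test_ion_transport_odds_lowers_subset_cpg(self, tmp_path):
        from copegen.cpg_metrics import compute_cpg_oe

        spec = SyntheticGenomeSpec(
            chrom_length=500_000, n_genes_per_chrom=40,
            ion_transport_cpg_odds=0.3, rng_seed=8,
        )
        truth = gen_genome(spec, tmp_path)
        ion = [compute_cpg_oe(g["cds"]).cpg_oe for g in truth["genes"]
               if "ion_transport" in g["labels"]]
        rest = [compute_cpg_oe(g["cds"]).cpg_oe for g in truth["genes"]
                if "ion_transport" not in g["labels"]]
        assert np.mean(ion) < np.mean(rest) - 0.1


class TestGenDepths:
    def test_null_model_outlier_rate_is_low(self, tmp_path):
        """With no duplicated genes, the k=3 fence flags <=1%."""
        spec = SyntheticGenomeSpec(
            depth_model=DepthModel(duplicated_fraction=0.0, n_genes=2000),
            rng_seed=13,
        )
        truth = gen_depths(spec, tmp_path)
        depths = {}
        for line in open(truth["file"]):
            g, d = line.split()
            depths[g] = float(d)
        recs = depth_outliers(depths, k=3.0)
        assert sum(r.outlier_high for r in recs) / len(recs) <= 0.01

    def test_truth_lists_duplicated_ids(self, tmp_path):
        spec = SyntheticGenomeSpec(rng_seed=3)
        truth = gen_depths(spec, tmp_path)
        assert len(truth["duplicated"]) == round(0.05 * 2000)

    def test_determinism(self, tmp_path):
        spec = SyntheticGenomeSpec(rng_seed=21)
        t1 = gen_depths(spec, tmp_path / "a")
        t2 = gen_depths(spec, tmp_path / "b")
        assert t1["duplicated"] == t2["duplicated"]
        assert _md5(tmp_path / "a" / "depths.tsv") == _md5(
            tmp_path / "b" / "depths.tsv")


class TestGenParalogs:
    def test_target_zero_gives_identical_pairs(self, tmp_path):
        from Bio import SeqIO

        spec = SyntheticGenomeSpec(
            paralog_model=ParalogModel(n_pairs=10, codons=50, target_ks=0.0),
            rng_seed=2,
        )
        gen_paralogs(spec, tmp_path)
        seqs = {r.id: str(r.seq)
                for r in SeqIO.parse(str(tmp_path / "pairs.fasta"), "fasta")}
        for pid in {i[:-2] for i in seqs}:
            assert seqs[pid + "_a"] == seqs[pid + "_b"]

    def test_copies_encode_same_protein(self, tmp_path):
        from Bio.Seq import Seq

        spec = SyntheticGenomeSpec(
            paralog_model=ParalogModel(n_pairs=10, codons=60, target_ks=0.3),
            rng_seed=4,
        )
        truth = gen_paralogs(spec, tmp_path)
        from Bio import SeqIO

        seqs = {r.id: str(r.seq)
                for r in SeqIO.parse(truth["file"], "fasta")}
        for pid in {i[:-2] for i in seqs}:
            assert (Seq(seqs[pid + "_a"]).translate()
                    == Seq(seqs[pid + "_b"]).translate())


class TestGenReads:
    def test_zero_coverage_writes_empty_file(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">c\n" + "ACGT" * 100 + "\n")
        fq = tmp_path / "r.fq"
        n = gen_reads(fa, fq, coverage=0, read_length=50, seed=1)
        assert n == 0 and fq.read_text() == ""

    def test_determinism(self, tmp_path, rng):
        genome = "".join(rng.choice(list("ACGT"), size=5000))
        fa = tmp_path / "g.fa"
        fa.write_text(">c\n" + genome + "\n")
        gen_reads(fa, tmp_path / "a.fq", coverage=5, read_length=100, seed=3)
        gen_reads(fa, tmp_path / "b.fq", coverage=5, read_length=100, seed=3)
        assert _md5(tmp_path / "a.fq") == _md5(tmp_path / "b.fq")

    def test_error_rate_perturbs_reads(self, tmp_path, rng):
        genome = "".join(rng.choice(list("ACGT"), size=2000))
        fa = tmp_path / "g.fa"
        fa.write_text(">c\n" + genome + "\n")
        gen_reads(fa, tmp_path / "e.fq", coverage=2, read_length=100,
                  error_rate=0.1, seed=3)
        gen_reads(fa, tmp_path / "c.fq", coverage=2, read_length=100,
                  error_rate=0.0, seed=3)
        assert _md5(tmp_path / "e.fq") != _md5(tmp_path / "c.fq")


class TestGenTraitTable:
    def test_group_medians_track_targets(self):
        t = gen_trait_table(
            {"Calanoida": (30, 3000.0), "Harpacticoida": (30, 300.0)},
            cv=0.3, seed=11,
        )
        from copegen.comparative_stats import group_medians

        med = group_medians(t)
        assert med["Calanoida"] == pytest.approx(3000, rel=0.3)
        assert med["Calanoida"] > 5 * med["Harpacticoida"]

    def test_tsv_roundtrip(self, tmp_path):
        out = tmp_path / "traits.tsv"
        t = gen_trait_table({"A": (5, 100.0), "B": (5, 50.0)}, seed=1,
                            out_tsv=out)
        from copegen.comparative_stats import TraitTable

        t2 = TraitTable.from_tsv(str(out))
        assert np.allclose(
            np.sort(t.df["value"].to_numpy()),
            np.sort(t2.df["value"].to_numpy()),
        )
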