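import numpy as np
import pytest

from copegen.synthetic_data import SyntheticGenomeSpec, gen_genome


@pytest.fixture(scope="session")
def small_spec():
    """A small seeded genome spec shared across tests: 4 chromosomes of
    500 kb, 30 genes each."""
    return SyntheticGenomeSpec(
        n_chromosomes=4,
        chrom_length=500_000,
        n_genes_per_chrom=30,
        rng_seed=101,
    )


@pytest.fixture(scope="session")
def small_genome(small_spec, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("genome")
    truth = gen_genome(small_spec, outdir)
    return outdir, truth


@pytest.fixture(scope="session")
def small_bundle(small_genome):
    from copegen.genome_io import load_genome

    outdir, truth = small_genome
    return load_genome(
        outdir / "genome.fasta",
        outdir / "genes.gff3",
        outdir / "labels.tsv",
        centromeres=truth["centromeres"],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
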