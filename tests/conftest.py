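import pytest

from plaqomics.simulate import (
    SimConfig,
    gen_annotation,
    gen_genome,
    simulate_reads,
)


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    """A fast synthetic study: 30 kb genome, 6 coding genes, 4 circles."""
    return SimConfig(
        seed=11,
        genome_length=30_000,
        n_coding_genes=6,
        n_lncrnas_per_class=2,
        n_circrnas=4,
        junction_reads_per_circ=2,
        n_linear_reads=300,
        n_features=300,
    )


@pytest.fixture(scope="session")
def small_genome(small_cfg):
    genome = gen_genome(small_cfg)
    annotation, truth = gen_annotation(genome, small_cfg)
    return genome, annotation, truth


@pytest.fixture(scope="session")
def small_reads(small_cfg, small_genome):
    genome, annotation, truth = small_genome
    return simulate_reads(genome, annotation, truth, small_cfg)
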