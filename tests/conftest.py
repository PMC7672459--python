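import pytest

from quadprobe import SimulationConfig, simulate_fixture


@pytest.fixture(scope="session")
def default_fixture():
    """The default synthetic study: 2 x 500 kb, 40 genes, 120 planted motifs."""
    return simulate_fixture(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_fixture():
    """A cheap fixture for unit-scale pipeline tests."""
    config = SimulationConfig(
        seed=7,
        n_chroms=1,
        chrom_length=100_000,
        n_genes=8,
        gene_length=3000,
        motif_counts={"4G": 8, "4GL15": 4, "GVBQ": 4, "Bulge": 4, "Hybrid2": 2, "Hybrid3": 2},
    )
    return simulate_fixture(config)
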