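import pytest

from retroscope import (
    UniformBias,
    build_toy_genome,
    generate_annotations,
    plant_integration_sites,
)


@pytest.fixture(scope="session")
def genome():
    """Two-chromosome 1 Mb toy genome shared across tests."""
    return build_toy_genome(2, [500_000, 500_000], seed=101)


@pytest.fixture(scope="session")
def annotations(genome):
    """Tss/Enh segments, five disjoint subcompartments, 50%-coverage LADs."""
    spec = {
        "Tss": (100, 200, 0.02),
        "Enh": (100, 400, 0.04),
        "A1": (20, 5_000, 0.10),
        "A2": (10, 2_500, 0.025),
        "B1": (10, 1_000, 0.01),
        "B2": (10, 1_000, 0.01),
        "B3": (10, 1_000, 0.01),
        "LAD": (25, 20_000, 0.50),
    }
    return generate_annotations(genome, spec, seed=202)


@pytest.fixture(scope="session")
def uniform_sites(genome):
    return plant_integration_sites(
        genome, None, 1000, UniformBias(), seed=303
    ).to_frame()
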