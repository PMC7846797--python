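import pytest

from sacs.synthetic_data import (
    PlantedSignature,
    SimulationConfig,
    simulate_dataset,
)

PLANTS = [
    PlantedSignature("H3K4me1", "H3K4me2", "upstream_200", "included", 5.0),
    PlantedSignature("H4K20me1", "H3K79me2", "exon_body", "excluded", 5.0),
    PlantedSignature("H4K20me1", "H4K91ac", "downstream_200", "mid_included", 5.0),
]


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated condition shared by read-only tests."""
    return simulate_dataset(SimulationConfig(seed=11, n_genes=150))


@pytest.fixture(scope="session")
def planted_dataset():
    """A condition with one planted signature (no genome, for speed)."""
    # >=150 member events in the planted group, the regime where
    # signature recovery is expected to succeed
    plant = PlantedSignature(
        "H4K20me1", "H3K79me2", "exon_body", "excluded", 5.0, member_fraction=0.7
    )
    return simulate_dataset(
        SimulationConfig(
            seed=7,
            n_genes=600,
            planted_signatures=[plant],
            make_genome=False,
        )
    )
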