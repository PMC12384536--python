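import pytest

from hybridase import SimulationConfig
from hybridase.simulate import ParentalReference, generate_parental_references


@pytest.fixture(scope="session")
def small_cfg() -> SimulationConfig:
    """A cheap but non-trivial simulation: 30 genes, 4k reads/sample."""
    return SimulationConfig(
        n_genes=30,
        transcript_length_range=(300, 500),
        divergence_rate=0.02,
        n_replicates_per_condition=2,
        reads_per_sample=4000,
        read_length=80,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_refs(small_cfg):
    return generate_parental_references(small_cfg)


@pytest.fixture()
def toy_refs():
    """Two handmade 2-transcript references sharing one transcript."""
    shared = "ACGTACGTACGTACGTACGT"
    only1 = "TTTTCCCCGGGGAAAATTTT"
    only2 = "GGGGTTTTAAAACCCCGGGG"
    ref1 = ParentalReference(
        "parent1", {"t1a": shared, "t1b": only1}, {"t1a": "g1", "t1b": "g2"}
    )
    ref2 = ParentalReference(
        "parent2", {"t2a": shared, "t2b": only2}, {"t2a": "h1", "t2b": "h2"}
    )
    return ref1, ref2
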