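import numpy as np
import pytest

from kdrscape import (
    Alignment,
    PopulationSet,
    SimConfig,
    paper_mimic_config,
    simulate_dataset,
)
from kdrscape.synth import Demography, neutral_layout


@pytest.fixture
def toy_aln():
    """Four 3-bp sequences with hand-enumerable pairwise differences."""
    return Alignment(["a", "b", "c", "d"], ["AAT", "AAT", "ACT", "GCT"])


@pytest.fixture
def toy_pops():
    return PopulationSet(
        {"a": "p1", "b": "p1", "c": "p2", "d": "p2"},
        {"p1": (20.0, 100.0), "p2": (25.0, 110.0)},
        {"p1": "west", "p2": "east"},
    )


@pytest.fixture(scope="session")
def mimic_bundle():
    """One deterministic paper-mimic dataset shared across tests."""
    cfg = paper_mimic_config(seed=11)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def small_neutral_bundle():
    """A small neutral two-deme dataset for structure/spatial tests."""
    cfg = SimConfig(
        n_demes=4,
        samples_per_deme=10,
        migration_rate=0.2,
        theta_per_site=0.01,
        layout=neutral_layout(400),
        demography=Demography(),
        seed=5,
    )
    return simulate_dataset(cfg)


def random_alignment(rng: np.random.Generator, n: int, L: int) -> Alignment:
    """Uniform random alignment (test helper, not a coalescent sample)."""
    arr = rng.choice(list("ACGT"), size=(n, L))
    return Alignment([f"s{i}" for i in range(n)], ["".join(r) for r in arr])
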