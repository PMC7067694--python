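import numpy as np
import pytest

from viromarker.simulate import (
    CategorySpec,
    PlantedPair,
    SimulationConfig,
    simulate_dataset,
)

TINY_CATEGORIES = [
    CategorySpec("NCLDV", "virus", 3, n_references=2),
    CategorySpec("ssRNA", "virus", 2, n_references=2),
    CategorySpec("host_bacteria", "host", 2, n_references=2),
]

TINY_PAIRS = [PlantedPair("ssRNA_cand00", "host_bacteria_cand00", 0.9)]


def tiny_config(seed: int = 0, **overrides) -> SimulationConfig:
    defaults = dict(
        seed=seed,
        n_samples=12,
        categories=list(TINY_CATEGORIES),
        planted_pairs=list(TINY_PAIRS),
        n_decoys=3,
        library_size_range=(300, 800),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def tiny_dataset():
    """A small noisy dataset shared across read-level tests."""
    return simulate_dataset(tiny_config(seed=11))


@pytest.fixture(scope="session")
def zero_noise_dataset():
    """Same structure with no marker mutation and no sequencing error."""
    return simulate_dataset(
        tiny_config(seed=12, contig_mutation_rate=0.0, error_rate=0.0)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
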