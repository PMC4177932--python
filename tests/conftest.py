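"""Shared fixtures: seeded synthetic libraries reused across test modules."""

import numpy as np
import pytest

from barcodegap.distances import build_distance_matrix
from barcodegap.synthetic_data import SimulationConfig, simulate_library


@pytest.fixture(scope="session")
def clean_library():
    """Default 100-species library, no anomalies (fixed seed)."""
    library, truth = simulate_library(SimulationConfig(n_species=100, seed=20140924))
    return library, truth


@pytest.fixture(scope="session")
def clean_matrix(clean_library):
    library, _ = clean_library
    return build_distance_matrix(library, model="K2P")


@pytest.fixture(scope="session")
def anomalous_library():
    """Library with 3 injected deep splits, 2 sharing pairs, 5 singletons."""
    config = SimulationConfig(
        n_species=100,
        seed=7041776,
        n_deep_split_species=3,
        n_shared_haplotype_pairs=2,
        n_singleton_species=5,
    )
    return simulate_library(config)


@pytest.fixture(scope="session")
def small_library():
    """30-specimen library for brute-force oracle comparisons."""
    library, _ = simulate_library(
        SimulationConfig(n_species=12, seed=42, intraspecific_scale=0.008)
    )
    rng = np.random.default_rng(1)
    keep = rng.choice(library.ids, size=min(30, len(library)), replace=False)
    return library.subset(sorted(keep))
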