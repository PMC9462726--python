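import numpy as np
import pytest

from sandpop.genotype_io import GenotypeMatrix
from sandpop.synthetic_data import (
    FamilySpec,
    IslandModelSpec,
    simulate_family_pairs,
    simulate_island_model,
)


@pytest.fixture(scope="session")
def island_matrix() -> GenotypeMatrix:
    """Three shallowly differentiated demes, desk scale."""
    return simulate_island_model(
        IslandModelSpec(n_pops=3, n_per_pop=(20, 25, 30), n_loci=400, fst=0.05,
                        missing_rate=0.02, seed=11)
    )


@pytest.fixture(scope="session")
def two_deme_matrix() -> GenotypeMatrix:
    """Two well-separated demes for network/clustering checks."""
    return simulate_island_model(
        IslandModelSpec(n_pops=2, n_per_pop=(25, 25), n_loci=1000, fst=0.1, seed=4)
    )


@pytest.fixture(scope="session")
def family_data():
    """Labelled relationship pairs at 2,000 informative loci."""
    spec = FamilySpec(n_loci=2000, n_unrelated=15, n_half_sib=8, n_full_sib=8,
                      n_parent_offspring=8, seed=2)
    return simulate_family_pairs(spec)


@pytest.fixture()
def tiny_matrix() -> GenotypeMatrix:
    """Hand-sized two-population matrix for exact-value checks."""
    calls = np.array([
        [0, 1, 2, 1],
        [2, 1, 0, 0],
        [1, 1, 2, 0],
        [0, 0, 2, 1],
        [2, 2, 1, 0],
        [1, 0, 1, 2],
    ], dtype=np.int16)
    return GenotypeMatrix(
        individual_ids=[f"i{k}" for k in range(6)],
        populations=["A", "A", "A", "B", "B", "B"],
        loci=["L1", "L2", "L3", "L4"],
        calls=calls,
    )
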