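import numpy as np
import pytest
from hypothesis import settings

from mosi import (
    BoldMatrix,
    MosiConfig,
    PlantedSpec,
    VoxelLattice,
    generate_planted_volume,
    grow_regions,
)

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_volume():
    """High-SNR 4-region volume: fast, near-deterministic structure."""
    return generate_planted_volume(
        PlantedSpec(dims=(8, 8, 4), n_regions=4, n_timepoints=100, snr=5.0, seed=21)
    )


@pytest.fixture(scope="session")
def two_level_volume():
    """3 networks x 2 regions, nested, moderate SNR."""
    return generate_planted_volume(
        PlantedSpec(
            dims=(10, 10, 4),
            n_networks=3,
            regions_per_network=2,
            n_timepoints=120,
            snr=2.0,
            seed=33,
        )
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_bold(lattice: VoxelLattice, data: np.ndarray) -> BoldMatrix:
    return BoldMatrix(np.asarray(data, dtype=float), lattice)
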