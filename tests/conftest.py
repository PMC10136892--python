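import numpy as np
import pytest

from radpet.grids import RoiMask, VoxelGrid
from radpet.synthetic import SyntheticConfig, generate_phantom

# Small grid for fast unit tests; the liver ellipsoid and lesions still fit.
TINY_GRID = (40, 40, 28)


@pytest.fixture
def tiny_config():
    return SyntheticConfig(n_patients=6, grid_shape=TINY_GRID, seed=7)


@pytest.fixture
def phantom(tiny_config):
    return generate_phantom(tiny_config, 0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def grid_from(values, spacing=(4.0, 4.0, 4.0)) -> VoxelGrid:
    """A VoxelGrid holding a 1-D value list laid out along one axis."""
    arr = np.asarray(values, dtype=float).reshape(1, -1, 1)
    return VoxelGrid(arr, spacing)


def full_mask(grid: VoxelGrid) -> RoiMask:
    return RoiMask(np.ones(grid.shape, dtype=bool), grid.spacing)
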