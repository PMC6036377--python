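import numpy as np
import pytest

from contourqa import StructureMask, VoxelGrid


@pytest.fixture
def rng():
    return np.random.default_rng(20260)


def random_mask(rng, max_dim=12, density=None, min_dim=2, spacing=None):
    """Random mask on a random small grid; density drawn from [0.05, 0.6]."""
    dims = rng.integers(min_dim, max_dim + 1, size=3)
    if spacing is None:
        spacing = rng.uniform(0.5, 3.0, size=3)
    if density is None:
        density = rng.uniform(0.05, 0.6)
    data = rng.random(tuple(dims)) < density
    return StructureMask(VoxelGrid(*dims, *spacing), data)


def nonempty_random_mask(rng, **kw):
    m = random_mask(rng, **kw)
    while m.is_empty:
        m = random_mask(rng, **kw)
    return m


@pytest.fixture
def unit_grid():
    def make(x, y, z, sx=1.0, sy=1.0, sz=1.0):
        return VoxelGrid(x, y, z, sx, sy, sz)

    return make


def mask_from_voxels(voxels, dims=(4, 4, 4), spacing=(1, 1, 1)):
    return StructureMask.from_voxels(VoxelGrid(*dims, *spacing), voxels)
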