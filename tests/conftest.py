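import numpy as np
import pytest

import homokappa as hk


@pytest.fixture
def grid20():
    """Mirror-closed 20^3 grid, 2 mm voxels, no midline voxel (even count)."""
    return hk.VolumeGrid.symmetric((20, 20, 20), 2.0)


@pytest.fixture
def grid_odd():
    """Mirror-closed grid with a voxel sheet exactly on the midline."""
    return hk.VolumeGrid.symmetric((11, 8, 8), 2.0)


@pytest.fixture
def packed_atlas(grid20):
    """4-pair synthetic atlas partitioning both hemispheres."""
    return hk.gen_synthetic_atlas(4, grid20, seed=11)


@pytest.fixture
def spaced_atlas():
    """8-pair spaced atlas on a 4 mm grid; regions farther apart than the
    default kernel truncation radius (no MA footprint overlap)."""
    grid = hk.VolumeGrid.symmetric((36, 24, 24), 4.0)
    return hk.gen_synthetic_atlas(8, grid, seed=3, style="spaced",
                                  min_gap_mm=24.0)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
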