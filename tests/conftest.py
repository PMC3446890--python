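import numpy as np
import pytest

from ttomo import (
    BrainMask,
    VoxelGrid,
    build_fraction_template,
    default_design,
    synthetic_brain_mask,
)


@pytest.fixture(scope="session")
def brain200():
    """Synthetic brain + reference design at 200 µm voxels (shared, read-only)."""
    mask = synthetic_brain_mask(voxel_size=200.0)
    design = default_design(mask.grid, mask, oblique_angle_deg=10.0)
    templates = [build_fraction_template(mask.grid, mask, s) for s in design]
    return mask, design, templates


@pytest.fixture()
def cube_grid():
    return VoxelGrid(shape=(16, 16, 16), voxel_size=100.0)


@pytest.fixture()
def cube_mask(cube_grid):
    return BrainMask(grid=cube_grid, inside=np.ones(cube_grid.shape, dtype=bool))
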