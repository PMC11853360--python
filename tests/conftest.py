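import numpy as np
import pytest

from petmuscle import Grid, MuscleRegion, generate_atlas


@pytest.fixture(scope="session")
def atlas():
    """Shared default atlas (4 mm grid); placement caches persist across tests."""
    return generate_atlas()


def make_cylinder_region(
    radius_mm: float = 30.0,
    height_mm: float = 200.0,
    spacing: float = 4.0,
    muscle: str = "quadriceps",
    pad_mm: float = 12.0,
) -> MuscleRegion:
    """Standalone cylindrical muscle around the z axis with a z-aligned bone.

    Used to exercise placement rules on geometry simple enough for brute-force
    oracles.
    """
    half_xy = radius_mm + pad_mm
    n_xy = int(2 * half_xy / spacing) + 1
    if n_xy % 2 == 0:  # keep a voxel center exactly on the cylinder axis
        n_xy += 1
    n_z = int((height_mm + 2 * pad_mm) / spacing) + 1
    origin = (-(n_xy - 1) / 2 * spacing, -(n_xy - 1) / 2 * spacing, -pad_mm)
    grid = Grid(shape=(n_xy, n_xy, n_z), spacing=spacing, origin=origin)
    xs = grid.axis_centers(0)[:, None, None]
    ys = grid.axis_centers(1)[None, :, None]
    zs = grid.axis_centers(2)[None, None, :]
    mask = (xs**2 + ys**2 <= radius_mm**2) & (zs >= 0) & (zs <= height_mm)
    return MuscleRegion(
        muscle=muscle,
        side="R",
        mask=mask,
        grid=grid,
        landmark_proximal=np.array([0.0, 0.0, height_mm]),
        landmark_distal=np.array([0.0, 0.0, 0.0]),
    )
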