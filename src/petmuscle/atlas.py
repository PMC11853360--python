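"""Stylized whole-body muscle atlas on a regular voxel grid.

The atlas provides everything the VOI-placement rules need from a CT-derived
segmentation: an integer label map with twelve muscle compartments (deltoid,
biceps brachii, triceps brachii, psoas, quadriceps, hamstrings; left and
right), bone-axis landmarks for each muscle, a vessel mask, a mediastinal
blood-pool reference compartment, and a soft-tissue body mask.  Geometry is
deliberately schematic — cylinders and an elliptic torso on a symmetric grid —
because only the topology matters: compartments are disjoint, left/right are
exact mirror images about the midsagittal plane, and every landmark lies
inside the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MUSCLES = ("deltoid", "biceps", "triceps", "psoas", "quadriceps", "hamstrings")
SIDES = ("R", "L")

#: muscles quantified with the large (20 mm) VOI; the rest use the small (10 mm) one
LARGE_VOI_MUSCLES = frozenset({"quadriceps", "hamstrings"})

BODY_CODE = 100


class AtlasSizeError(ValueError):
    """Grid too coarse/small to embed the muscle compartments."""


@dataclass(frozen=True)
class Grid:
    """Regular isotropic voxel grid with world coordinates in mm (RAS-like).

    World position of voxel index (i, j, k) is ``origin + index * spacing``.
    """

    shape: tuple[int, int, int]
    spacing: float
    origin: tuple[float, float, float]

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(idx, dtype=float) * self.spacing

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Nearest voxel index for a world position (not bounds-checked)."""
        rel = (np.asarray(xyz, dtype=float) - np.asarray(self.origin)) / self.spacing
        return np.rint(rel).astype(int)

    def contains_world(self, xyz) -> bool:
        idx = (np.asarray(xyz, dtype=float) - np.asarray(self.origin)) / self.spacing
        return bool(np.all(idx > -0.5) and np.all(idx < np.asarray(self.shape) - 0.5))

    @property
    def affine(self) -> np.ndarray:
        a = np.diag([self.spacing] * 3 + [1.0])
        a[:3, 3] = self.origin
        return a

    def axis_centers(self, axis: int) -> np.ndarray:
        return self.origin[axis] + np.arange(self.shape[axis]) * self.spacing


@dataclass
class MuscleRegion:
    """One side-specific muscle: mask, grid and its bone-axis landmarks."""

    muscle: str
    side: str
    mask: np.ndarray  # bool
    grid: Grid
    landmark_proximal: np.ndarray  # world mm
    landmark_distal: np.ndarray  # world mm
    plane_point: np.ndarray | None = None  # overrides the fractional plane rule (psoas L5–S1)
    _feas_cache: dict = field(default_factory=dict, repr=False)

    @property
    def bone_length_mm(self) -> float:
        return float(np.linalg.norm(self.landmark_distal - self.landmark_proximal))

    @property
    def voxel_indices(self) -> np.ndarray:
        return np.argwhere(self.mask)


@dataclass
class MuscleAtlas:
    """Label map plus the side structures the placement rules consume."""

    grid: Grid
    labels: np.ndarray  # int16; 0 = air, BODY_CODE = non-muscle soft tissue
    label_codes: dict  # (muscle, side) -> int
    vessel_mask: np.ndarray  # bool
    reference_mask: np.ndarray  # bool (mediastinal blood-pool analog)
    landmarks: dict  # (muscle, side) -> (proximal_xyz, distal_xyz) world mm
    l5s1_point: np.ndarray  # world mm, lumbosacral junction
    muscle_radius_mm: dict  # muscle -> nominal cylinder radius (generator sizing aid)
    _regions: dict = field(default_factory=dict, repr=False)

    def mask(self, muscle: str, side: str) -> np.ndarray:
        return self.labels == self.label_codes[(muscle, side)]

    def region(self, muscle: str, side: str) -> MuscleRegion:
        key = (muscle, side)
        if key not in self._regions:
            prox, dist = self.landmarks[key]
            self._regions[key] = MuscleRegion(
                muscle=muscle,
                side=side,
                mask=self.mask(muscle, side),
                grid=self.grid,
                landmark_proximal=np.asarray(prox, dtype=float),
                landmark_distal=np.asarray(dist, dtype=float),
                plane_point=(np.asarray(self.l5s1_point, dtype=float) if muscle == "psoas" else None),
            )
        return self._regions[key]

    def body_mask(self) -> np.ndarray:
        return self.labels > 0

    def voi_diameter(self, muscle: str, large_mm: float = 20.0, small_mm: float = 10.0) -> float:
        return large_mm if muscle in LARGE_VOI_MUSCLES else small_mm


def _mirror_x(mask: np.ndarray) -> np.ndarray:
    """Reflect a mask about the midsagittal plane (x axis index 0)."""
    return mask[::-1, :, :].copy()


def _cylinder(grid: Grid, cx: float, cy: float, r: float, z0: float, z1: float) -> np.ndarray:
    """Axial cylinder mask: (x-cx)^2 + (y-cy)^2 <= r^2, z0 <= z <= z1."""
    xs = grid.axis_centers(0)[:, None, None]
    ys = grid.axis_centers(1)[None, :, None]
    zs = grid.axis_centers(2)[None, None, :]
    return ((xs - cx) ** 2 + (ys - cy) ** 2 <= r**2) & (zs >= z0) & (zs <= z1)


def _elliptic_cylinder(grid: Grid, cx, cy, rx, ry, z0, z1) -> np.ndarray:
    xs = grid.axis_centers(0)[:, None, None]
    ys = grid.axis_centers(1)[None, :, None]
    zs = grid.axis_centers(2)[None, None, :]
    return (((xs - cx) / rx) ** 2 + ((ys - cy) / ry) ** 2 <= 1.0) & (zs >= z0) & (zs <= z1)


# World-mm layout (right side; left is the x-mirror).  z grows foot→head-ward
# within the modeled trunk-and-limbs span.
_LAYOUT = {
    # muscle: (cx, cy, radius, z0, z1)
    "quadriceps": (60.0, 28.0, 24.0, 60.0, 380.0),
    "hamstrings": (60.0, -28.0, 24.0, 60.0, 380.0),
    "psoas": (30.0, 0.0, 15.0, 400.0, 480.0),
    "deltoid": (112.0, 0.0, 20.0, 504.0, 560.0),
    "biceps": (112.0, 18.0, 14.0, 340.0, 500.0),
    "triceps": (112.0, -18.0, 14.0, 340.0, 500.0),
}

_BONES = {
    # muscle: (proximal_xyz, distal_xyz), right side
    "quadriceps": ((60.0, 0.0, 380.0), (60.0, 0.0, 60.0)),  # femur
    "hamstrings": ((60.0, 0.0, 380.0), (60.0, 0.0, 60.0)),  # femur
    "deltoid": ((112.0, 0.0, 560.0), (112.0, 0.0, 320.0)),  # humerus
    "biceps": ((112.0, 0.0, 560.0), (112.0, 0.0, 320.0)),  # humerus
    "triceps": ((112.0, 0.0, 560.0), (112.0, 0.0, 320.0)),  # humerus
    "psoas": ((30.0, 0.0, 480.0), (30.0, 0.0, 400.0)),  # lumbar span
}

_L5S1 = (0.0, 0.0, 440.0)

_WORLD_X = 152.0  # half-extent, mm
_WORLD_Y = 62.0
_WORLD_Z = (0.0, 624.0)


def generate_atlas(spacing: float = 4.0, min_voxels_per_muscle: int = 100) -> MuscleAtlas:
    """Build the deterministic stylized atlas at the requested voxel pitch.

    Parameters
    ----------
    spacing
        Isotropic voxel size in mm (default 4, a typical reconstructed PET grid).
    min_voxels_per_muscle
        Sizing guard: every compartment must contain at least this many voxels,
        otherwise an :class:`AtlasSizeError` is raised.
    """
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    nx = int(np.floor(2 * _WORLD_X / spacing)) + 1
    if nx % 2 == 0:  # keep the grid exactly symmetric about x = 0
        nx -= 1
    ny = int(np.floor(2 * _WORLD_Y / spacing)) + 1
    nz = int(np.floor((_WORLD_Z[1] - _WORLD_Z[0]) / spacing)) + 1
    origin = (-(nx - 1) / 2.0 * spacing, -(ny - 1) / 2.0 * spacing, _WORLD_Z[0] + spacing / 2.0)
    grid = Grid(shape=(nx, ny, nz), spacing=float(spacing), origin=origin)

    labels = np.zeros(grid.shape, dtype=np.int16)
    codes: dict = {}
    landmarks: dict = {}
    radii: dict = {}
    code = 0
    for muscle in MUSCLES:
        cx, cy, r, z0, z1 = _LAYOUT[muscle]
        radii[muscle] = r
        right = _cylinder(grid, cx, cy, r, z0, z1)
        for side, mask in (("R", right), ("L", _mirror_x(right))):
            code += 1
            if int(mask.sum()) < min_voxels_per_muscle:
                raise AtlasSizeError(
                    f"{muscle} {side}: only {int(mask.sum())} voxels at spacing "
                    f"{spacing} mm (< {min_voxels_per_muscle}); grid too coarse"
                )
            if np.any(labels[mask] != 0):
                raise AtlasSizeError(f"{muscle} {side} overlaps another compartment")
            labels[mask] = code
            codes[(muscle, side)] = code
            prox, dist = _BONES[muscle]
            if side == "L":
                prox = (-prox[0], prox[1], prox[2])
                dist = (-dist[0], dist[1], dist[2])
            for p in (prox, dist):
                if not grid.contains_world(p):
                    raise AtlasSizeError(f"landmark {p} of {muscle} {side} outside grid")
            landmarks[(muscle, side)] = (np.asarray(prox), np.asarray(dist))

    # Vessels: central aorta-like rod plus femoral rods between quad and hamstrings.
    vessel = _cylinder(grid, 0.0, 0.0, 8.0, 400.0, 620.0)
    fem_r = _cylinder(grid, 38.0, 0.0, 4.0, 40.0, 400.0)
    vessel |= fem_r | _mirror_x(fem_r)
    # Mediastinal blood-pool reference: a dedicated segment of the central rod.
    reference = _cylinder(grid, 0.0, 0.0, 8.0, 540.0, 580.0)
    vessel |= reference

    # Soft-tissue body envelope (torso + limbs); labels only where not muscle/vessel.
    body = _elliptic_cylinder(grid, 0.0, 0.0, 70.0, 45.0, 380.0, _WORLD_Z[1])
    body |= _cylinder(grid, 60.0, 0.0, 55.0, 40.0, 390.0)
    body |= _cylinder(grid, -60.0, 0.0, 55.0, 40.0, 390.0)
    body |= _cylinder(grid, 112.0, 0.0, 36.0, 310.0, 570.0)
    body |= _cylinder(grid, -112.0, 0.0, 36.0, 310.0, 570.0)
    body |= vessel
    labels[body & (labels == 0)] = BODY_CODE

    return MuscleAtlas(
        grid=grid,
        labels=labels,
        label_codes=codes,
        vessel_mask=vessel,
        reference_mask=reference,
        landmarks=landmarks,
        l5s1_point=np.asarray(_L5S1, dtype=float),
        muscle_radius_mm=radii,
    )
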