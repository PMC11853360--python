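"""Spherical VOI placement: fixed anatomical position vs. uptake hotspot.

Two placement procedures are implemented and compared downstream:

* **fixed** — the VOI sits on the muscle's cross-section centroid in a plane
  orthogonal to the bone axis at a muscle-specific fraction of the bone length
  (biceps/triceps/quadriceps/hamstrings: 50% of humerus/femur; deltoid: 10%
  from the proximal humerus; psoas: the plane through the lumbosacral L5–S1
  junction).
* **hotspot** — the VOI sits on the highest-uptake voxel of the muscle whose
  prominence is confirmed on consecutive neighboring slices (an
  anti-coincidence rule: k consecutive slices on at least one side must show
  similarly high uptake near the candidate's in-plane position).

Both procedures then shift the center minimally so the sphere lies fully
inside the muscle and clear of vessels; ties are broken deterministically.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_dilation, binary_erosion

from .atlas import Grid, MuscleRegion
from .suv import SUVVolume, _sphere_offsets

log = logging.getLogger(__name__)

#: fraction of proximal->distal bone length defining the fixed target plane
FIXED_PLANE_FRACTION = {
    "biceps": 0.5,
    "triceps": 0.5,
    "quadriceps": 0.5,
    "hamstrings": 0.5,
    "deltoid": 0.1,  # "upper part" of the humerus
}


class PlacementError(RuntimeError):
    """No feasible VOI center satisfying the in-muscle/vessel-free constraints."""


@dataclass(frozen=True)
class VOI:
    """A spherical volume of interest."""

    center_mm: tuple
    diameter_mm: float
    muscle: str
    side: str
    method: str  # "fixed" | "hotspot"
    fallback: bool = False  # hotspot confirmation found no candidate


@dataclass(frozen=True)
class HotspotParams:
    """Consecutive-slice confirmation parameters for the hotspot search."""

    k_slices: int = 2  # consecutive slices that must confirm, on one side
    tau: float = 0.8  # similarity fraction of the candidate SUV
    inplane_radius_mm: float = 15.0  # in-plane search radius around the candidate
    axis: int = 2  # slice axis (2 = axial)

    def __post_init__(self):
        if self.k_slices < 1:
            raise ValueError("k_slices must be >= 1")
        if not 0.0 < self.tau <= 1.0:
            raise ValueError("tau must lie in (0, 1]")


def _sphere_structure(diameter_mm: float, spacing: float) -> np.ndarray:
    oi, oj, ok = _sphere_offsets(diameter_mm / 2.0, spacing)
    r = int(max(np.max(np.abs(oi)), np.max(np.abs(oj)), np.max(np.abs(ok)), 0))
    size = 2 * r + 1
    s = np.zeros((size, size, size), dtype=bool)
    s[oi + r, oj + r, ok + r] = True
    return s


def feasible_centers(region: MuscleRegion, diameter_mm: float, vessel_mask: np.ndarray | None) -> np.ndarray:
    """Boolean mask of voxel centers where the VOI sphere is fully in-muscle
    and intersects no vessel voxel.  Cached per region and diameter for the
    default (None = no vessels) case and for atlas-held regions.
    """
    key = (float(diameter_mm), id(vessel_mask))
    cached = region._feas_cache.get(key)
    if cached is not None:
        return cached
    structure = _sphere_structure(diameter_mm, region.grid.spacing)
    feas = binary_erosion(region.mask, structure=structure, border_value=0)
    if vessel_mask is not None and vessel_mask.any():
        feas &= ~binary_dilation(vessel_mask, structure=structure)
    region._feas_cache[key] = feas
    return feas


def _nearest_feasible(
    feas: np.ndarray,
    target_mm: np.ndarray,
    grid: Grid,
    tiebreak_mm: np.ndarray | None = None,
    restrict: np.ndarray | None = None,
) -> np.ndarray | None:
    """Feasible voxel center closest to ``target_mm``.

    Ties on the primary distance are broken by distance to ``tiebreak_mm``
    (when given), then lexicographically by voxel index.
    """
    mask = feas if restrict is None else (feas & restrict)
    cand = np.argwhere(mask)
    if cand.shape[0] == 0:
        return None
    centers = cand * grid.spacing + np.asarray(grid.origin)
    d = np.linalg.norm(centers - target_mm, axis=1)
    d = np.round(d, 6)  # stabilize float ties
    best = d == d.min()
    cand, centers = cand[best], centers[best]
    if tiebreak_mm is not None and cand.shape[0] > 1:
        d2 = np.round(np.linalg.norm(centers - tiebreak_mm, axis=1), 6)
        best2 = d2 == d2.min()
        cand, centers = cand[best2], centers[best2]
    order = np.lexsort((cand[:, 2], cand[:, 1], cand[:, 0]))
    return centers[order[0]]


def _axial_coordinate(region: MuscleRegion, points_mm: np.ndarray) -> np.ndarray:
    """Projection of points onto the unit bone axis (proximal -> distal)."""
    axis = region.landmark_distal - region.landmark_proximal
    axis = axis / np.linalg.norm(axis)
    return (points_mm - region.landmark_proximal) @ axis


def fixed_target_plane(region: MuscleRegion, fraction: float | None = None) -> tuple[np.ndarray, float]:
    """Target point on the bone axis and the axial coordinate of its plane.

    ``fraction`` defaults to the muscle's rule; a psoas-style ``plane_point``
    on the region overrides the fractional rule.
    """
    if region.plane_point is not None:
        t = float(_axial_coordinate(region, region.plane_point[None, :])[0])
        axis = region.landmark_distal - region.landmark_proximal
        axis = axis / np.linalg.norm(axis)
        return region.landmark_proximal + t * axis, t
    if fraction is None:
        fraction = FIXED_PLANE_FRACTION.get(region.muscle, 0.5)
    point = region.landmark_proximal + fraction * (region.landmark_distal - region.landmark_proximal)
    return point, float(fraction * region.bone_length_mm)


def place_fixed_voi(
    region: MuscleRegion,
    diameter_mm: float,
    vessel_mask: np.ndarray | None = None,
    fraction: float | None = None,
    axial_tolerance_fraction: float = 0.1,
) -> VOI:
    """Place the fixed anatomical VOI.

    The center starts at the centroid of the muscle cross-section in the
    target plane and moves minimally (ties toward the centroid, then
    lexicographic) to the nearest position where the sphere is in-muscle and
    vessel-free.  Raises :class:`PlacementError` when no feasible center
    exists within +-``axial_tolerance_fraction`` of the bone length along
    the axis.
    """
    grid = region.grid
    idx = region.voxel_indices
    if idx.shape[0] == 0:
        raise PlacementError(f"{region.muscle} {region.side}: empty muscle mask")
    centers = idx * grid.spacing + np.asarray(grid.origin)
    target_point, t_target = fixed_target_plane(region, fraction)
    ax = _axial_coordinate(region, centers)

    # cross-section = in-muscle voxels within half a voxel of the target plane
    half = grid.spacing / 2.0 + 1e-9
    tol = axial_tolerance_fraction * region.bone_length_mm
    sect = np.abs(ax - t_target) <= half
    if not sect.any():
        sect = np.abs(ax - t_target) <= tol
        if not sect.any():
            raise PlacementError(
                f"{region.muscle} {region.side}: no muscle cross-section near the target plane"
            )
    centroid = centers[sect].mean(axis=0)

    feas = feasible_centers(region, diameter_mm, vessel_mask)
    band = np.zeros(grid.shape, dtype=bool)
    in_band = np.abs(ax - t_target) <= tol + 1e-9
    band[idx[in_band, 0], idx[in_band, 1], idx[in_band, 2]] = True
    best = _nearest_feasible(feas, centroid, grid, tiebreak_mm=centroid, restrict=band)
    if best is None:
        raise PlacementError(
            f"{region.muscle} {region.side}: no feasible {diameter_mm:.0f} mm VOI center "
            f"within +-{axial_tolerance_fraction:.0%} of the bone length"
        )
    return VOI(tuple(best), float(diameter_mm), region.muscle, region.side, "fixed")


def confirm_candidate(
    suv: SUVVolume,
    candidate_idx,
    muscle_mask: np.ndarray,
    params: HotspotParams = HotspotParams(),
) -> bool:
    """Consecutive-slice confirmation of a hotspot candidate.

    True iff, in the ``k`` consecutive slices immediately before OR after the
    candidate's slice along the confirmation axis, every slice contains an
    in-muscle voxel within the in-plane radius whose SUV is >= tau times the
    candidate's SUV.  A side with fewer than k slices available cannot
    confirm; if neither side has k slices the candidate is rejected.
    """
    i, j, k = (int(v) for v in candidate_idx)
    axis = params.axis
    grid = suv.grid
    cval = suv.values[i, j, k]
    threshold = params.tau * cval

    idx = np.array([i, j, k])
    s = idx[axis]
    n_slices = grid.shape[axis]
    inplane_axes = [a for a in range(3) if a != axis]
    r_vox = int(np.floor(params.inplane_radius_mm / grid.spacing + 1e-9))

    def slice_ok(s2: int) -> bool:
        sl: list = [slice(None)] * 3
        sl[axis] = s2
        bounds = {}
        for a in inplane_axes:
            lo = max(int(idx[a]) - r_vox, 0)
            hi = min(int(idx[a]) + r_vox + 1, grid.shape[a])
            sl[a] = slice(lo, hi)
            bounds[a] = (lo, hi)
        sub = suv.values[tuple(sl)]  # 2D: (inplane_axes[0], inplane_axes[1])
        msub = muscle_mask[tuple(sl)]
        a0, a1 = inplane_axes
        d0 = (np.arange(*bounds[a0]) - idx[a0]) * grid.spacing
        d1 = (np.arange(*bounds[a1]) - idx[a1]) * grid.spacing
        circ = d0[:, None] ** 2 + d1[None, :] ** 2 <= params.inplane_radius_mm**2 + 1e-9
        vals = sub[circ & msub]
        return vals.size > 0 and float(vals.max()) >= threshold

    for direction in (-1, +1):
        lo_s = s + direction * params.k_slices
        if lo_s < 0 or lo_s >= n_slices:
            continue  # fewer than k slices on this side
        if all(slice_ok(s + direction * step) for step in range(1, params.k_slices + 1)):
            return True
    return False


def place_hotspot_voi(
    suv: SUVVolume,
    region: MuscleRegion,
    diameter_mm: float,
    params: HotspotParams = HotspotParams(),
    vessel_mask: np.ndarray | None = None,
    max_candidates: int | None = None,
) -> VOI:
    """Place the hotspot VOI on the highest confirmed-uptake voxel.

    In-muscle voxels are ranked by SUV descending (ties lexicographic by
    index); the first candidate passing consecutive-slice confirmation wins.
    If no candidate is confirmed the global in-muscle maximum is used and the
    VOI is flagged (``fallback=True``) with a logged warning.  The center is
    then adjusted minimally to an in-muscle, vessel-free position exactly as
    for the fixed method.
    """
    grid = region.grid
    idx = region.voxel_indices
    if idx.shape[0] == 0:
        raise PlacementError(f"{region.muscle} {region.side}: empty muscle mask")
    vals = suv.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    # descending SUV, ties lexicographic by (i, j, k)
    order = np.lexsort((idx[:, 2], idx[:, 1], idx[:, 0], -vals))
    if max_candidates is not None:
        order = order[:max_candidates]

    chosen = None
    fallback = False
    for o in order:
        if confirm_candidate(suv, idx[o], region.mask, params):
            chosen = idx[o]
            break
    if chosen is None:
        chosen = idx[order[0]]
        fallback = True
        log.warning(
            "%s %s: no hotspot candidate passed consecutive-slice confirmation; "
            "falling back to the global in-muscle maximum",
            region.muscle,
            region.side,
        )

    target = chosen * grid.spacing + np.asarray(grid.origin)
    feas = feasible_centers(region, diameter_mm, vessel_mask)
    best = _nearest_feasible(feas, target, grid, tiebreak_mm=target)
    if best is None:
        raise PlacementError(
            f"{region.muscle} {region.side}: no feasible {diameter_mm:.0f} mm VOI center"
        )
    return VOI(tuple(best), float(diameter_mm), region.muscle, region.side, "hotspot", fallback)
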