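"""SUV conversion and spherical-VOI uptake statistics.

SUV here is the body-weight variant: ``SUV = C * W / D`` with the activity
concentration C in kBq/mL, body weight W in kg and injected dose D in MBq
(units cancel under the 1 g/mL tissue-density convention).  SUV_peak is the
maximum, over VOI voxels, of the mean uptake in a small spherical
neighborhood (default diameter 12 mm, roughly the common 1 mL convention);
it trades a little of SUV_max's sensitivity for robustness to noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .atlas import Grid


class EmptyVOIError(ValueError):
    """The VOI sphere contains no voxel centers (e.g. lies outside the grid)."""


@dataclass(frozen=True)
class SUVVolume:
    """Dimensionless body-weight-normalized uptake on a regular grid."""

    values: np.ndarray
    grid: Grid


@dataclass(frozen=True)
class SUVStats:
    """Uptake statistics read from one VOI."""

    suv_max: float
    suv_mean: float
    suv_peak: float
    n_voxels: int
    d_peak_mm: float


def to_suv(activity: np.ndarray, dose_mbq: float, weight_kg: float, grid: Grid | None = None) -> SUVVolume | np.ndarray:
    """Convert an activity-concentration volume (kBq/mL) to SUV.

    Returns an :class:`SUVVolume` when ``grid`` is given, otherwise the bare
    array (convenient for scalar checks).
    """
    if dose_mbq <= 0:
        raise ValueError("injected dose must be positive")
    if weight_kg <= 0:
        raise ValueError("body weight must be positive")
    values = np.asarray(activity, dtype=float) * (weight_kg / dose_mbq)
    if grid is None:
        return values
    return SUVVolume(values=values, grid=grid)


@lru_cache(maxsize=64)
def _sphere_offsets(radius_mm: float, spacing: float) -> tuple[np.ndarray, ...]:
    """Voxel-index offsets whose centers lie within radius_mm (inclusive)."""
    r_vox = int(np.floor(radius_mm / spacing + 0.5))
    rng = np.arange(-r_vox, r_vox + 1)
    ii, jj, kk = np.meshgrid(rng, rng, rng, indexing="ij")
    keep = (ii**2 + jj**2 + kk**2) * spacing**2 <= radius_mm**2 + 1e-9
    return (ii[keep], jj[keep], kk[keep])


def sphere_voxels(center_mm, diameter_mm: float, grid: Grid) -> np.ndarray:
    """Indices (n, 3) of voxels whose centers lie within diameter/2 of ``center_mm``.

    Membership is by voxel-center inclusion (no partial-volume weighting), so
    the result is translation-equivariant on the grid and bit-reproducible.
    """
    if diameter_mm <= 0:
        raise ValueError("diameter must be positive")
    center = np.asarray(center_mm, dtype=float)
    r = diameter_mm / 2.0
    lo = np.ceil((center - r - np.asarray(grid.origin)) / grid.spacing - 1e-9).astype(int)
    hi = np.floor((center + r - np.asarray(grid.origin)) / grid.spacing + 1e-9).astype(int)
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, np.asarray(grid.shape) - 1)
    if np.any(hi < lo):
        raise EmptyVOIError(f"VOI at {center} (d={diameter_mm} mm) contains no voxels")
    axes = [np.arange(a, b + 1) for a, b in zip(lo, hi)]
    ii, jj, kk = np.meshgrid(*axes, indexing="ij")
    idx = np.stack([ii.ravel(), jj.ravel(), kk.ravel()], axis=1)
    d2 = np.sum((idx * grid.spacing + np.asarray(grid.origin) - center) ** 2, axis=1)
    idx = idx[d2 <= r**2 + 1e-9]
    if idx.shape[0] == 0:
        raise EmptyVOIError(f"VOI at {center} (d={diameter_mm} mm) contains no voxels")
    return idx


def _neighborhood_means(values: np.ndarray, idx: np.ndarray, d_peak_mm: float, grid: Grid) -> np.ndarray:
    """Mean SUV in the d_peak sphere around each voxel in ``idx``.

    The neighborhood may extend beyond the VOI; parts outside the grid are
    clipped (the mean runs over the in-grid neighborhood voxels only).
    """
    if d_peak_mm <= 0:
        return values[idx[:, 0], idx[:, 1], idx[:, 2]]
    oi, oj, ok = _sphere_offsets(d_peak_mm / 2.0, grid.spacing)
    shape = np.asarray(grid.shape)
    out = np.empty(idx.shape[0])
    for n, (i, j, k) in enumerate(idx):
        ni, nj, nk = i + oi, j + oj, k + ok
        keep = (
            (ni >= 0) & (ni < shape[0]) & (nj >= 0) & (nj < shape[1]) & (nk >= 0) & (nk < shape[2])
        )
        out[n] = values[ni[keep], nj[keep], nk[keep]].mean()
    return out


def suv_stats(suv: SUVVolume, center_mm, diameter_mm: float, d_peak_mm: float = 12.0) -> SUVStats:
    """SUV_max, SUV_mean and SUV_peak inside a spherical VOI.

    SUV_peak is the maximum over VOI voxels of the mean SUV in a sphere of
    diameter ``d_peak_mm`` centered on the voxel; with a degenerate
    neighborhood (d_peak -> 0) it equals SUV_max.
    """
    idx = sphere_voxels(center_mm, diameter_mm, suv.grid)
    vals = suv.values[idx[:, 0], idx[:, 1], idx[:, 2]]
    peak = float(np.max(_neighborhood_means(suv.values, idx, d_peak_mm, suv.grid)))
    return SUVStats(
        suv_max=float(vals.max()),
        suv_mean=float(vals.mean()),
        suv_peak=peak,
        n_voxels=int(idx.shape[0]),
        d_peak_mm=float(d_peak_mm),
    )
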