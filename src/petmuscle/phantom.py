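"""Digital whole-body PET phantoms with known per-muscle ground truth.

A phantom is built in SUV space: each muscle gets a baseline uptake scaled by
its subject's disease-group multiplier, optional focal lesions are added, and
non-muscle compartments get fixed physiological values (blood pool 1.5, soft
tissue 0.4, air 0).  The SUV field is converted to an activity concentration
(kBq/mL) through the inverse body-weight SUV relation C = SUV * D / W, then
degraded by an isotropic Gaussian point-spread blur and activity-proportional
Gaussian noise.  Ground truth (pattern class, focus centers, noiseless
pre-blur maximum SUV) is recorded before any degradation.

Foci are parabolic caps: within radius R of the center the added uptake is
``A * (1 - 0.5 * (d/R)^2)``, so the focus maximum A sits exactly at the
recorded center and the edge still carries half the amplitude (a sharp-edged
lesion with a mild apex, which keeps the hottest voxel unambiguous on a
coarse grid).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import binary_erosion, gaussian_filter

from .atlas import BODY_CODE, MUSCLES, SIDES, Grid, MuscleAtlas, generate_atlas

GROUPS = ("control", "RA", "OA", "IIM")

#: default within-group uptake multipliers (control < RA < OA < IIM)
DEFAULT_MULTIPLIERS = {"control": 1.0, "RA": 1.1, "OA": 1.4, "IIM": 2.0}

#: default group sizes of the emulated cohort
DEFAULT_GROUP_SIZES = {"control": 8, "RA": 11, "OA": 10, "IIM": 10}

#: group median body weights (kg) used to sample subjects
GROUP_WEIGHT_KG = {"control": 69.0, "RA": 66.0, "OA": 83.5, "IIM": 78.7}

DEFAULT_FOCUS_AMPLITUDE = 2.0  # SUV above baseline
FOCUS_CAP_GAMMA = 0.5  # parabolic-cap shape factor

PATTERNS = ("homogeneous", "unifocal", "multifocal", "diffuse")


class FocusPlacementError(ValueError):
    """A focus of the requested radius cannot be placed inside the muscle."""


@dataclass(frozen=True)
class SubjectParams:
    """Per-subject physiology and dosimetry."""

    weight_kg: float
    dose_mbq: float
    group: str = "control"
    multiplier: float = 1.0
    baseline_suv: float = 1.0  # resting muscle uptake before group scaling
    blood_suv: float = 1.5  # blood pool / vessels
    body_suv: float = 0.4  # non-muscle soft tissue

    def __post_init__(self):
        if self.weight_kg <= 0 or self.dose_mbq <= 0:
            raise ValueError("weight and dose must be positive")
        if self.multiplier <= 0:
            raise ValueError("multiplier must be positive")


@dataclass(frozen=True)
class PatternSpec:
    """Uptake pattern for one muscle compartment.

    ``centers`` may fix world-mm focus positions; ``None`` samples them
    uniformly from voxels where the whole focus fits inside the muscle.
    """

    pattern: str = "homogeneous"
    n_foci: int = 0
    amplitude: float = DEFAULT_FOCUS_AMPLITUDE
    radius_mm: float = 12.0
    centers: tuple | None = None
    #: unifocal-default amplitude at the same disease severity; bounds diffuse foci
    reference_amplitude: float = DEFAULT_FOCUS_AMPLITUDE

    def __post_init__(self):
        if self.pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}")
        n = self.n_foci
        ok = {
            "homogeneous": n == 0,
            "unifocal": n == 1,
            "multifocal": n >= 2,
            "diffuse": n >= 5,
        }[self.pattern]
        if not ok:
            raise ValueError(f"pattern {self.pattern!r} incompatible with n_foci={n}")
        if self.pattern == "diffuse" and self.amplitude > 0.5 * self.reference_amplitude:
            raise ValueError(
                "diffuse foci must be low-amplitude "
                f"(<= {0.5 * self.reference_amplitude} SUV)"
            )

    @property
    def heterogeneous(self) -> bool:
        return self.pattern != "homogeneous"


#: nominal muscle radius below which multifocal defaults drop to two foci
_SMALL_MUSCLE_RADIUS_MM = 22.0


def default_pattern(
    pattern: str,
    muscle_radius_mm: float,
    rng: np.random.Generator | None = None,
    amplitude_scale: float = 1.0,
) -> PatternSpec:
    """Standard spec for a pattern class, with focus size scaled to the muscle.

    ``amplitude_scale`` scales the focal amplitudes with disease severity
    (the cohort generator passes the group multiplier, so the whole uptake
    field — baseline and lesions — carries the group fold-difference).
    """
    amp = DEFAULT_FOCUS_AMPLITUDE * amplitude_scale
    if pattern == "homogeneous":
        return PatternSpec("homogeneous", 0)
    if pattern == "unifocal":
        return PatternSpec("unifocal", 1, amp, 0.6 * muscle_radius_mm, reference_amplitude=amp)
    if pattern == "multifocal":
        if muscle_radius_mm < _SMALL_MUSCLE_RADIUS_MM:
            n = 2  # larger counts no longer fit without overlapping
        else:
            n = 3 if rng is None else int(rng.integers(2, 5))
        return PatternSpec("multifocal", n, amp, 0.45 * muscle_radius_mm, reference_amplitude=amp)
    if pattern == "diffuse":
        return PatternSpec(
            "diffuse", 12, 0.5 * amp * 0.7, 0.35 * muscle_radius_mm, reference_amplitude=amp
        )
    raise ValueError(f"unknown pattern {pattern!r}")


@dataclass
class MuscleTruth:
    """Pre-blur, pre-noise ground truth for one muscle compartment."""

    muscle: str
    side: str
    pattern: str
    n_foci: int
    focus_centers: np.ndarray  # (n, 3) world mm
    amplitude: float
    radius_mm: float
    baseline_suv: float  # after group multiplier
    true_max_suv: float  # noiseless, pre-blur in-muscle maximum


@dataclass
class PhantomVolume:
    """Reconstructed-activity stand-in plus everything needed to analyze it."""

    activity: np.ndarray  # kBq/mL, float
    atlas: MuscleAtlas
    subject: SubjectParams
    truth: dict  # (muscle, side) -> MuscleTruth
    psf_fwhm_mm: float
    noise_coeff: float
    seed: int
    subject_id: str = "phantom"

    @property
    def grid(self) -> Grid:
        return self.atlas.grid


def _sphere_offsets_vox(radius_mm: float, spacing: float) -> np.ndarray:
    r_vox = int(np.floor(radius_mm / spacing))
    rng = np.arange(-r_vox, r_vox + 1)
    ii, jj, kk = np.meshgrid(rng, rng, rng, indexing="ij")
    d2 = (ii**2 + jj**2 + kk**2) * spacing**2
    keep = d2 <= radius_mm**2
    return np.stack([ii[keep], jj[keep], kk[keep]], axis=1)


def _focus_fit_mask(mask: np.ndarray, radius_mm: float, spacing: float) -> np.ndarray:
    """Voxels where a sphere of radius_mm (voxel-center membership) fits in the mask."""
    offs = _sphere_offsets_vox(radius_mm, spacing)
    r = int(np.max(np.abs(offs)))
    size = 2 * r + 1
    structure = np.zeros((size, size, size), dtype=bool)
    structure[offs[:, 0] + r, offs[:, 1] + r, offs[:, 2] + r] = True
    return binary_erosion(mask, structure=structure, border_value=0)


def _sample_focus_centers(
    mask: np.ndarray,
    grid: Grid,
    spec: PatternSpec,
    rng: np.random.Generator,
    muscle: str,
    side: str,
) -> np.ndarray:
    fit = _focus_fit_mask(mask, spec.radius_mm, grid.spacing)
    cand = np.argwhere(fit)
    if cand.shape[0] == 0:
        raise FocusPlacementError(
            f"focus radius {spec.radius_mm:.1f} mm does not fit inside {muscle} {side}"
        )
    # two voxel pitches of clearance: a single-voxel gap can still be bridged
    # by 26-connected diagonals (sqrt(3) * spacing), merging discrete foci
    min_sep = 2.0 * spec.radius_mm + 2.0 * grid.spacing
    # diffuse foci are allowed to overlap (they model a smeared elevation);
    # discrete unifocal/multifocal foci must stay disjoint
    seps = (min_sep, 0.5 * min_sep, 0.0) if spec.pattern == "diffuse" else (min_sep,)
    cand_mm = cand * grid.spacing + np.asarray(grid.origin)
    for sep in seps:
        # restart-based sampling: an unlucky first draw can leave no room for
        # the rest, so redraw the whole configuration rather than one focus
        for _restart in range(100):
            centers: list[np.ndarray] = []
            feasible = np.ones(cand_mm.shape[0], dtype=bool)
            for _ in range(spec.n_foci):
                idx_f = np.flatnonzero(feasible)
                if idx_f.size == 0:
                    break
                c = cand_mm[idx_f[rng.integers(idx_f.size)]]
                centers.append(c)
                feasible &= np.linalg.norm(cand_mm - c, axis=1) >= sep
            if len(centers) == spec.n_foci:
                return np.asarray(centers, dtype=float)
    raise FocusPlacementError(
        f"could not place {spec.n_foci} disjoint foci of radius "
        f"{spec.radius_mm:.1f} mm in {muscle} {side}"
    )


def _add_focus(suv: np.ndarray, mask: np.ndarray, grid: Grid, center: np.ndarray, amplitude: float, radius_mm: float) -> None:
    """Add a parabolic-cap focus, restricted to the muscle mask."""
    lo = grid.world_to_index(center - radius_mm) - 1
    hi = grid.world_to_index(center + radius_mm) + 2
    lo = np.maximum(lo, 0)
    hi = np.minimum(hi, grid.shape)
    sl = tuple(slice(a, b) for a, b in zip(lo, hi))
    idx = np.stack(
        np.meshgrid(*[np.arange(a, b) for a, b in zip(lo, hi)], indexing="ij"), axis=-1
    )
    d2 = np.sum((idx * grid.spacing + np.asarray(grid.origin) - center) ** 2, axis=-1)
    inside = (d2 <= radius_mm**2) & mask[sl]
    add = amplitude * (1.0 - FOCUS_CAP_GAMMA * d2 / radius_mm**2)
    suv[sl][inside] += add[inside]


def generate_phantom(
    atlas: MuscleAtlas,
    subject: SubjectParams,
    patterns: dict,
    seed: int,
    psf_fwhm_mm: float = 6.0,
    noise_coeff: float = 0.05,
    subject_id: str = "phantom",
) -> PhantomVolume:
    """Synthesize one whole-body activity volume.

    Parameters
    ----------
    patterns
        Mapping ``(muscle, side) -> PatternSpec``; missing compartments default
        to homogeneous.
    seed
        Seeds focus sampling and noise; identical seeds give bit-identical output.
    psf_fwhm_mm
        Isotropic Gaussian point-spread FWHM applied to the activity volume (0 = none).
    noise_coeff
        Per-voxel Gaussian noise variance = coeff * activity (kBq/mL units),
        applied after the blur and clipped at zero.
    """
    rng = np.random.default_rng(seed)
    grid = atlas.grid
    suv = np.zeros(grid.shape, dtype=np.float64)
    suv[atlas.labels == BODY_CODE] = subject.body_suv
    suv[atlas.vessel_mask | atlas.reference_mask] = subject.blood_suv

    truth: dict = {}
    for muscle in MUSCLES:
        for side in SIDES:
            spec = patterns.get((muscle, side), PatternSpec())
            mask = atlas.mask(muscle, side)
            base = subject.baseline_suv * subject.multiplier
            suv[mask] = base
            if spec.n_foci > 0:
                if spec.centers is not None:
                    centers = np.asarray(spec.centers, dtype=float).reshape(-1, 3)
                    fit = _focus_fit_mask(mask, spec.radius_mm, grid.spacing)
                    for c in centers:
                        ci = grid.world_to_index(c)
                        if not fit[tuple(ci)]:
                            raise FocusPlacementError(
                                f"focus at {c} (radius {spec.radius_mm} mm) does not fit "
                                f"inside {muscle} {side}"
                            )
                else:
                    centers = _sample_focus_centers(mask, grid, spec, rng, muscle, side)
                for c in centers:
                    _add_focus(suv, mask, grid, c, spec.amplitude, spec.radius_mm)
            else:
                centers = np.zeros((0, 3))
            truth[(muscle, side)] = MuscleTruth(
                muscle=muscle,
                side=side,
                pattern=spec.pattern,
                n_foci=spec.n_foci,
                focus_centers=centers,
                amplitude=spec.amplitude if spec.n_foci else 0.0,
                radius_mm=spec.radius_mm if spec.n_foci else 0.0,
                baseline_suv=base,
                true_max_suv=float(suv[mask].max()),
            )

    activity = suv * (subject.dose_mbq / subject.weight_kg)
    if psf_fwhm_mm > 0:
        sigma_vox = psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / grid.spacing
        activity = gaussian_filter(activity, sigma=sigma_vox, mode="constant")
    if noise_coeff > 0:
        noise = rng.standard_normal(activity.shape) * np.sqrt(noise_coeff * np.maximum(activity, 0.0))
        activity = np.clip(activity + noise, 0.0, None)

    return PhantomVolume(
        activity=activity,
        atlas=atlas,
        subject=subject,
        truth=truth,
        psf_fwhm_mm=psf_fwhm_mm,
        noise_coeff=noise_coeff,
        seed=seed,
        subject_id=subject_id,
    )


# --------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class CohortConfig:
    """Study-level configuration for a synthetic cohort.

    ``het_prob`` gives the probability that a muscle group shows a
    heterogeneous pattern, per disease group, separately for the thigh
    muscles (quadriceps/hamstrings, which are nearly always heterogeneous)
    and the remaining muscles.  Pattern class is drawn once per muscle group
    and shared by the left and right compartments; focus positions on the
    left are mirrored from the right (``mirror_lr``), emulating the broadly
    symmetric uptake of these diseases.
    """

    group_sizes: tuple = tuple(DEFAULT_GROUP_SIZES[g] for g in GROUPS)
    multipliers: tuple = tuple(DEFAULT_MULTIPLIERS[g] for g in GROUPS)
    het_prob_thigh: tuple = (0.75, 1.0, 1.0, 1.0)
    het_prob_other: tuple = (0.15, 0.65, 0.55, 0.65)
    subtype_probs: tuple = (0.4, 0.4, 0.2)  # unifocal, multifocal, diffuse
    psf_fwhm_mm: float = 6.0
    noise_coeff: float = 0.05
    spacing_mm: float = 4.0
    mirror_lr: bool = True
    master_seed: int = 0

    def __post_init__(self):
        if any(n < 1 for n in self.group_sizes):
            raise ValueError("group sizes must be >= 1")
        for p in (*self.het_prob_thigh, *self.het_prob_other):
            if not 0.0 <= p <= 1.0:
                raise ValueError("pattern probabilities must lie in [0, 1]")


def _mirror_center(c: np.ndarray) -> np.ndarray:
    return np.array([-c[0], c[1], c[2]])


def draw_subject_patterns(atlas: MuscleAtlas, config: CohortConfig, gi: int, rng: np.random.Generator) -> dict:
    """Draw a per-muscle pattern assignment for one subject."""
    patterns: dict = {}
    for muscle in MUSCLES:
        thigh = muscle in ("quadriceps", "hamstrings")
        p_het = (config.het_prob_thigh if thigh else config.het_prob_other)[gi]
        if rng.random() < p_het:
            sub = ("unifocal", "multifocal", "diffuse")[
                int(rng.choice(3, p=np.asarray(config.subtype_probs) / np.sum(config.subtype_probs)))
            ]
        else:
            sub = "homogeneous"
        spec_r = default_pattern(
            sub, atlas.muscle_radius_mm[muscle], rng, amplitude_scale=config.multipliers[gi]
        )
        if spec_r.n_foci > 0:
            centers_r = _sample_focus_centers(
                atlas.mask(muscle, "R"), atlas.grid, spec_r, rng, muscle, "R"
            )
            patterns[(muscle, "R")] = replace(spec_r, centers=tuple(map(tuple, centers_r)))
            if config.mirror_lr:
                centers_l = np.array([_mirror_center(c) for c in centers_r])
            else:
                centers_l = _sample_focus_centers(
                    atlas.mask(muscle, "L"), atlas.grid, spec_r, rng, muscle, "L"
                )
            patterns[(muscle, "L")] = replace(spec_r, centers=tuple(map(tuple, centers_l)))
        else:
            patterns[(muscle, "R")] = spec_r
            patterns[(muscle, "L")] = spec_r
    return patterns


def generate_cohort(config: CohortConfig, atlas: MuscleAtlas | None = None):
    """Generate the full phantom cohort.

    Returns ``(phantoms, truth_table)`` where the truth table is a DataFrame
    with one row per subject x muscle x side listing the true pattern and the
    noiseless pre-blur maximum SUV.
    """
    if atlas is None:
        atlas = generate_atlas(spacing=config.spacing_mm)
    ss = np.random.SeedSequence(config.master_seed)
    n_total = int(np.sum(config.group_sizes))
    children = ss.spawn(n_total)

    phantoms: list[PhantomVolume] = []
    rows = []
    idx = 0
    for gi, group in enumerate(GROUPS):
        for si in range(config.group_sizes[gi]):
            child = children[idx]
            seed = int(child.generate_state(1)[0] % (2**31))
            rng = np.random.default_rng(child)
            weight = float(np.clip(rng.normal(GROUP_WEIGHT_KG[group], 10.0), 45.0, 120.0))
            dose = 3.5 * weight * float(rng.uniform(0.95, 1.05))
            subject = SubjectParams(
                weight_kg=weight,
                dose_mbq=dose,
                group=group,
                multiplier=config.multipliers[gi],
            )
            patterns = draw_subject_patterns(atlas, config, gi, rng)
            sid = f"{group}_{si:02d}"
            ph = generate_phantom(
                atlas,
                subject,
                patterns,
                seed=seed,
                psf_fwhm_mm=config.psf_fwhm_mm,
                noise_coeff=config.noise_coeff,
                subject_id=sid,
            )
            phantoms.append(ph)
            for (muscle, side), t in ph.truth.items():
                rows.append(
                    {
                        "subject": sid,
                        "group": group,
                        "muscle": muscle,
                        "side": side,
                        "pattern": t.pattern,
                        "n_foci": t.n_foci,
                        "baseline_suv": t.baseline_suv,
                        "true_max_suv": t.true_max_suv,
                    }
                )
            idx += 1
    truth_table = pd.DataFrame(rows)
    return phantoms, truth_table
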