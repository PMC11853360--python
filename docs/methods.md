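# Methods

## The measurement model

The quantity of interest is the body-weight standardised uptake value of
[¹⁸F]-FDG in skeletal muscle. Given a reconstructed activity-concentration
volume C (kBq/mL), injected dose D (MBq) and body weight W (kg),

    SUV(v) = C(v) · W / D,

dimensionless under the 1 g/mL tissue-density convention. The package works
on the already-reconstructed, attenuation/scatter/decay-corrected volume;
scanner physics and reconstruction are out of scope (the phantom plays the
role of the corrected volume).

Uptake is read from spherical VOIs by three statistics: SUV_max (hottest
voxel), SUV_mean, and **SUV_peak** — the maximum over VOI voxels of the mean
SUV in a sphere of diameter `d_peak` centered on the voxel. `d_peak`
defaults to 12 mm (≈ 1 mL, the common convention); the peak neighborhood may
extend beyond the VOI and is clipped at the grid boundary. Two consequences
are worth knowing: with `d_peak → 0`, SUV_peak = SUV_max; and because the
neighborhood can leave the VOI, SUV_peak is *not* bounded by the in-VOI
SUV_max in general (a small VOI beside a hot region, or noise outside a
small VOI, can push a neighborhood mean above the in-VOI maximum). On
hotspot-placed VOIs, which contain the uptake maximum, the inequality
SUV_peak ≤ SUV_max holds.

Sphere membership everywhere is by voxel-center inclusion (a voxel belongs
to the sphere iff its center lies within the radius, boundary inclusive).
This forgoes partial-volume weighting in exchange for translation
equivariance and bit-exact reproducibility.

## VOI placement

**Fixed anatomical method.** The target plane is orthogonal to the bone axis
at a muscle-specific fraction of the proximal→distal length: 50 % of the
humerus for biceps/triceps, 50 % of the femur for quadriceps/hamstrings,
10 % from the proximal humerus for the deltoid ("upper part"; the fraction
is configurable), and the plane through the lumbosacral (L5–S1) junction for
the psoas. The VOI center starts at the centroid of the muscle cross-section
in that plane and moves the minimal Euclidean distance to a position where
the sphere lies fully in-muscle and intersects no vessel voxel. Ties are
broken toward the centroid, then lexicographically by voxel index. If no
feasible center exists within ±10 % of the bone length along the axis, a
placement error names the muscle.

**Hotspot method.** In-muscle voxels are ranked by SUV descending (ties
lexicographic). A candidate in slice s is *confirmed* iff in the k
consecutive slices immediately before s, or the k after (k = 2), every slice
has an in-muscle voxel within r = 15 mm in-plane whose SUV is at least
τ = 0.8 of the candidate's. The VOI is centered on the highest confirmed
candidate and then adjusted exactly as above. τ and r quantify "similar
increased uptake on consecutive slices"; no published threshold exists, so
both are configuration values. The visual procedure inspects axial, sagittal
and coronal planes; since a 3D ranked search dominates any per-plane search,
the implementation searches in 3D and confirms along one configurable axis
(default axial), preserving the anti-coincidence intent. If no candidate
confirms (e.g. a muscle thinner than k slices), the global in-muscle maximum
is used and the VOI is flagged — placement never fails on a non-empty
muscle.

**Hotspot vs fixed.** On noiseless phantoms with discrete (unifocal or
multifocal) foci, SUV_peak(hotspot) ≥ SUV_peak(fixed) for every muscle, and
the two methods agree exactly on homogeneous phantoms. The inequality is
*not* guaranteed for diffuse patterns: overlapping low-amplitude foci can
put the best 12-mm-neighborhood mean away from the hottest voxel, and the
hotspot rule — like the visual procedure it mirrors — centers on the hottest
confirmed voxel, not on the best neighborhood. In practice the shortfall is
small (≲ 0.2 SUV on default diffuse phantoms, < 2 % of muscles overall).

## Qualitative scoring

Positivity is SUV_peak ≥ blood-pool reference (boundary inclusive), with the
reference taken as the mean SUV of the mediastinal blood-pool compartment.
Pattern classification replaces two blinded readers with a deterministic
statistic: the in-muscle coefficient of variation CV = SD/mean. CV ≤ 0.15
reads homogeneous; otherwise the voxels above mean + 2·SD are grouped by
26-connectivity (robust to diagonal adjacency on coarse grids) and the
component count sets the subtype — 1 unifocal, ≥ 2 multifocal, 0 diffuse
(elevated variability without discrete hot components). The thresholds
(cv = 0.15, z = 2) are configuration values calibrated on the synthetic
cohort; this is a documented stand-in, not a validated clinical classifier,
and how visual readers separate "diffuse" from noise has no published
operationalization.

## Statistics

All p-values are two-sided, α = 0.05, stars * p<0.05 ** p<0.01 *** p<0.001.
Left/right symmetry uses the classical paired t test per muscle and method;
averaging of the two sides proceeds regardless of the test outcome (one
side is kept when the other is missing, flagged). Method agreement uses
Pearson (and Spearman) correlation with R² = r², and Bland–Altman analysis
of d = fixed − hotspot against the pair means: bias = mean(d), limits
bias ± 1.96·SD(d); the identity upper − lower = 3.92·SD holds for every
output. Group comparison is gated: ANOVA iff every group passes
Shapiro–Wilk (p ≥ 0.05) *and* the variance-homogeneity test passes,
otherwise Kruskal–Wallis (tie-corrected H, χ² reference). The gate's
variance test is the classical two-group variance-ratio F test, extended to
four groups by testing the max-ratio pair (the classical F test is
ill-defined beyond two groups); Levene's test is available as a configurable
alternative. Post-hoc contrasts use Dunn's rank test with tie correction,

    z_ij = (r̄_i − r̄_j) / sqrt[(N(N+1)/12 − Σ(t³−t)/(12(N−1))) (1/n_i + 1/n_j)],

Bonferroni-adjusted by default ("none" available). Standard tests delegate
to scipy.stats; Dunn's test and Bland–Altman are implemented here and
cross-checked against hand-computed oracles in the test suite.

## The synthetic phantom

The generator emulates the statistical structure the analysis assumes, not
anatomy. A 4 mm isotropic grid (typical reconstructed PET resolution;
configurable) holds twelve cylinder-based muscle compartments — deltoid,
biceps, triceps, psoas, quadriceps, hamstrings, left/right mirrored exactly
about the midsagittal plane — plus bone landmarks, an aorta-and-femoral
vessel tree, a mediastinal blood-pool compartment (SUV 1.5), and a
soft-tissue body envelope (SUV 0.4).

A phantom is built in SUV space: per-muscle baseline (default 1.0, resting
muscle) times the subject's disease-group multiplier, plus focal lesions.
Foci are parabolic caps, A·(1 − 0.5 (d/R)²) for d ≤ R: a sharp-edged lesion
with a mild apex whose maximum A sits exactly at the recorded center voxel,
keeping the hottest voxel unambiguous on a coarse grid (a perfectly flat
sphere would create a tie plateau and make "center recovery" ill-posed).
Pattern defaults, with R_m the muscle's nominal radius: unifocal — one
focus, amplitude 2.0 SUV, radius 0.6 R_m; multifocal — 2–4 disjoint foci
(2 in small muscles) at 0.45 R_m; diffuse — 12 overlapping foci at 0.35 R_m
with amplitude capped at half the unifocal default. Discrete foci keep
≥ 2 voxel pitches of clearance so 26-connected components cannot bridge.
The SUV field is converted to activity by the inverse SUV relation, blurred
with an isotropic Gaussian PSF (FWHM 6 mm default), then degraded with
Gaussian noise of variance = coefficient × activity (default 0.05,
≈ 10 % SUV noise at SUV 1 for a typical D/W of 5), clipped at zero — a
simple stand-in for post-reconstruction PET noise. Ground truth (pattern,
focus centers, pre-blur in-muscle maximum) is recorded before degradation,
which defines the recovery target unambiguously.

Cohorts default to 8 controls / 11 RA / 10 OA / 10 IIM with uptake
multipliers 1.0 / 1.1 / 1.4 / 2.0. The multiplier scales the whole field —
baseline *and* focal amplitudes — so group fold-differences in SUV_peak
track the multiplier and pattern classification behaves identically across
groups (an amplitude fixed in absolute SUV would wash out relative contrast
in high-uptake groups). Heterogeneity probabilities default to 0.75/1/1/1
(thigh muscles) and 0.15/0.65/0.55/0.65 (other muscles) per group,
subtype mix 0.4/0.4/0.2 unifocal/multifocal/diffuse — chosen to mirror the
reported visual pattern frequencies. The pattern class is drawn once per
muscle group and shared by both sides, with left focus positions mirrored
from the right, emulating the broadly symmetric uptake of these diseases.
Per-subject seeds spawn deterministically from the master seed: identical
configuration ⇒ bit-identical cohort.

What the phantom does **not** model: real anatomy and CT appearance,
axially varying noise from different per-bed acquisition times, respiratory
motion, inter-reader variability, and the true spatial texture of myositis.
Passing tests therefore demonstrate the correctness and calibration of the
*analysis machinery* under controlled conditions, not clinical performance.

## Numerical choices and degenerate inputs

Voxel grids are isotropic with world coordinates in mm; the x = 0 plane
falls exactly between mirrored voxel columns so left/right reflection is an
index flip. All tie-breaks (hotspot candidates, VOI adjustment) are
lexicographic by voxel index after rounding distances to 1e-6 mm,
making every placement bit-reproducible. Feasible VOI centers are
precomputed per muscle and diameter by binary erosion with the sphere
footprint (and dilation of the vessel mask), cached on the atlas. Degenerate
inputs raise typed errors: non-positive dose/weight, empty VOI spheres,
zero-variance paired differences, zero-mean muscles (undefined CV),
identical-value rank tests, and muscles that cannot hold the requested
sphere or focus.

## Problem sizes used in the checks

The test suite and acceptance script scale cohort counts to keep full runs
fast while leaving the generative conditions (pattern mix, noise, blur,
multipliers, 4 mm grid) at their defaults: the method-bias direction is
checked on twenty 8-subject default cohorts, hotspot dominance on ~50
noiseless single-subject phantoms, ground-truth recovery on noiseless
blur-free 8-subject cohorts, and group-ordering on twenty full 39-subject
cohorts; the Kruskal–Wallis null calibration uses 1000 replicates at the
study's group sizes.
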