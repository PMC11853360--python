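"""End-to-end study orchestration on a phantom cohort.

``run_study`` reproduces the full analysis chain: simulate a cohort,
quantify every muscle with both VOI methods, test and average left/right,
score uptake patterns against the blood-pool reference, compare the two
placement methods (correlation + Bland–Altman), compare disease groups
(gated ANOVA / Kruskal–Wallis with Dunn post-hoc), and summarize how well
the analysis recovers the generator's ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .atlas import MUSCLES, SIDES, MuscleAtlas, generate_atlas
from .phantom import GROUPS, CohortConfig, PhantomVolume, generate_cohort
from .qualitative import PatternTable, classify_pattern, positivity, tabulate
from .stats import (
    BlandAltmanResult,
    CorrelationResult,
    DegenerateInputError,
    GroupTestResult,
    bland_altman,
    correlation,
    group_compare,
    paired_t,
)
from .suv import SUVVolume, suv_stats, to_suv
from .voi import VOI, HotspotParams, place_fixed_voi, place_hotspot_voi

log = logging.getLogger(__name__)

METHODS = ("fixed", "hotspot")


@dataclass(frozen=True)
class StudyConfig:
    """Everything needed to run one synthetic study end to end."""

    cohort: CohortConfig = CohortConfig()
    diameter_large_mm: float = 20.0  # quadriceps, hamstrings
    diameter_small_mm: float = 10.0  # deltoid, biceps, triceps, psoas
    hotspot: HotspotParams = HotspotParams()
    d_peak_mm: float = 12.0
    cv_threshold: float = 0.15
    z_foci: float = 2.0
    methods: tuple = METHODS


@dataclass
class StudyReport:
    """All tables produced by one study run."""

    suv_table: pd.DataFrame  # per subject x muscle x side x method
    symmetry: pd.DataFrame  # L vs R paired t per muscle x method
    averaged: pd.DataFrame  # L/R-averaged SUV_peak per subject x muscle x method
    pattern_scores: pd.DataFrame
    pattern_table: PatternTable
    method_comparison: pd.DataFrame  # per muscle + pooled: r, R2, BA bias/limits
    group_tests: dict  # muscle -> GroupTestResult (hotspot, averaged SUV_peak)
    recovery: pd.DataFrame
    vois: list = field(default_factory=list)


def quantify_phantom(
    phantom: PhantomVolume,
    methods=METHODS,
    diameter_large_mm: float = 20.0,
    diameter_small_mm: float = 10.0,
    hotspot_params: HotspotParams = HotspotParams(),
    d_peak_mm: float = 12.0,
    muscles=MUSCLES,
) -> tuple[pd.DataFrame, list]:
    """Extract SUV statistics for every muscle with the requested methods.

    Returns (rows, vois): one row per muscle x side x method with SUV_max,
    SUV_mean and SUV_peak, plus the placed VOI objects.
    """
    atlas = phantom.atlas
    suv = to_suv(phantom.activity, phantom.subject.dose_mbq, phantom.subject.weight_kg, atlas.grid)
    rows = []
    vois: list[VOI] = []
    for muscle in muscles:
        diameter = atlas.voi_diameter(muscle, diameter_large_mm, diameter_small_mm)
        for side in SIDES:
            region = atlas.region(muscle, side)
            for method in methods:
                if method == "fixed":
                    voi = place_fixed_voi(region, diameter, vessel_mask=atlas.vessel_mask)
                else:
                    voi = place_hotspot_voi(
                        suv, region, diameter, params=hotspot_params, vessel_mask=atlas.vessel_mask
                    )
                st = suv_stats(suv, voi.center_mm, voi.diameter_mm, d_peak_mm)
                rows.append(
                    {
                        "subject": phantom.subject_id,
                        "group": phantom.subject.group,
                        "muscle": muscle,
                        "side": side,
                        "method": method,
                        "center_x_mm": voi.center_mm[0],
                        "center_y_mm": voi.center_mm[1],
                        "center_z_mm": voi.center_mm[2],
                        "diameter_mm": voi.diameter_mm,
                        "suv_max": st.suv_max,
                        "suv_mean": st.suv_mean,
                        "suv_peak": st.suv_peak,
                        "n_voxels": st.n_voxels,
                        "fallback": voi.fallback,
                    }
                )
                vois.append(voi)
    return pd.DataFrame(rows), vois


def reference_suv(phantom: PhantomVolume) -> float:
    """Mean SUV over the blood-pool reference compartment."""
    suv = to_suv(phantom.activity, phantom.subject.dose_mbq, phantom.subject.weight_kg)
    return float(suv[phantom.atlas.reference_mask].mean())


def average_lr(suv_table: pd.DataFrame, value: str = "suv_peak"):
    """Average left/right per subject x muscle x method, and test symmetry.

    The paired t test (left vs right, across subjects) is reported per muscle
    and method but never blocks averaging.  A subject missing one side keeps
    the available side's value, flagged in the ``n_sides`` column.  Muscles
    absent on both sides are dropped with a warning.
    """
    t = suv_table.copy()
    wide = t.pivot_table(
        index=["subject", "group", "muscle", "method"], columns="side", values=value, aggfunc="first"
    ).reset_index()
    for side in SIDES:
        if side not in wide.columns:
            wide[side] = np.nan
    both_missing = wide["L"].isna() & wide["R"].isna()
    if both_missing.any():
        for _, row in wide[both_missing].iterrows():
            log.warning("%s %s: muscle absent on both sides, excluded", row["subject"], row["muscle"])
        wide = wide[~both_missing]
    wide["averaged"] = wide[["L", "R"]].mean(axis=1)  # (L+R)/2, or the available side
    wide["n_sides"] = wide[["L", "R"]].notna().sum(axis=1)

    sym_rows = []
    for (muscle, method), grp in wide.groupby(["muscle", "method"]):
        pairs = grp.dropna(subset=["L", "R"])
        if len(pairs) < 2:
            continue
        try:
            res = paired_t(pairs["L"].to_numpy(), pairs["R"].to_numpy())
            sym_rows.append(
                {"muscle": muscle, "method": method, "t": res.t, "p": res.p,
                 "mean_diff_lr": res.mean_diff, "n": res.n, "degenerate": False}
            )
        except DegenerateInputError:
            d = (pairs["L"] - pairs["R"]).to_numpy()
            sym_rows.append(
                {"muscle": muscle, "method": method, "t": 0.0, "p": 1.0,
                 "mean_diff_lr": float(d.mean()), "n": len(pairs), "degenerate": True}
            )
    symmetry = pd.DataFrame(sym_rows)
    averaged = wide[["subject", "group", "muscle", "method", "averaged", "n_sides"]].rename(
        columns={"averaged": value}
    )
    return averaged, symmetry


def compare_methods(averaged: pd.DataFrame, value: str = "suv_peak") -> pd.DataFrame:
    """Fixed-vs-hotspot agreement per muscle and pooled over all muscles.

    Differences are oriented fixed - hotspot.  Reports Pearson and Spearman
    correlation (as R^2) and the Bland–Altman bias with 95% limits.
    """
    wide = averaged.pivot_table(
        index=["subject", "group", "muscle"], columns="method", values=value, aggfunc="first"
    ).reset_index().dropna(subset=["fixed", "hotspot"])
    rows = []
    scopes = [("pooled", wide)] + [(m, wide[wide["muscle"] == m]) for m in wide["muscle"].unique()]
    for name, df in scopes:
        if len(df) < 3:
            continue
        a = df["fixed"].to_numpy()
        b = df["hotspot"].to_numpy()
        ba = bland_altman(a, b)
        row = {"scope": name, "n": ba.n, "bias": ba.bias, "sd": ba.sd,
               "lower": ba.lower, "upper": ba.upper}
        for meth in ("pearson", "spearman"):
            try:
                c = correlation(a, b, meth)
                row[f"{meth}_r"] = c.r
                row[f"{meth}_r2"] = c.r2
                row[f"{meth}_p"] = c.p
            except DegenerateInputError:
                row[f"{meth}_r"] = np.nan
                row[f"{meth}_r2"] = np.nan
                row[f"{meth}_p"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def score_patterns(phantoms, config: StudyConfig, suv_table: pd.DataFrame) -> pd.DataFrame:
    """Classify every muscle's uptake pattern and positivity."""
    peak_lookup = suv_table[suv_table["method"] == "hotspot"].set_index(["subject", "muscle", "side"])["suv_peak"]
    rows = []
    for ph in phantoms:
        suv = to_suv(ph.activity, ph.subject.dose_mbq, ph.subject.weight_kg, ph.atlas.grid)
        ref = float(suv.values[ph.atlas.reference_mask].mean())
        for muscle in MUSCLES:
            for side in SIDES:
                mask = ph.atlas.mask(muscle, side)
                try:
                    peak = float(peak_lookup.loc[(ph.subject_id, muscle, side)])
                except KeyError:
                    peak = np.nan
                pos = int(peak >= ref) if np.isfinite(peak) else 0
                score = classify_pattern(
                    suv, mask, muscle, side,
                    cv_threshold=config.cv_threshold, z=config.z_foci, positivity_score=pos,
                )
                truth = ph.truth[(muscle, side)]
                rows.append(
                    {
                        "subject": ph.subject_id, "group": ph.subject.group,
                        "muscle": muscle, "side": side,
                        "pattern": score.pattern, "subtype": score.subtype,
                        "cv": score.cv, "focus_count": score.focus_count,
                        "positivity": score.positivity, "reference_suv": ref,
                        "true_pattern": truth.pattern,
                        "true_class": "heterogeneous" if truth.pattern != "homogeneous" else "homogeneous",
                    }
                )
    return pd.DataFrame(rows)


def recovery_summary(phantoms, suv_table: pd.DataFrame, vois, pattern_scores: pd.DataFrame) -> pd.DataFrame:
    """Ground-truth recovery: hotspot-center error, SUV_peak error, pattern hit.

    Center error is the distance from the hotspot VOI center to the nearest
    true focus center (unifocal/multifocal muscles only); SUV_peak error is
    hotspot SUV_peak minus the true pre-blur in-muscle maximum.
    """
    truth = {(p.subject_id, m, s): p.truth[(m, s)] for p in phantoms for m, s in p.truth}
    voi_lookup = {}
    hot = suv_table[suv_table["method"] == "hotspot"]
    for _, r in hot.iterrows():
        voi_lookup[(r["subject"], r["muscle"], r["side"])] = (
            np.array([r["center_x_mm"], r["center_y_mm"], r["center_z_mm"]]),
            r["suv_peak"],
        )
    cls = pattern_scores.set_index(["subject", "muscle", "side"])
    rows = []
    for key, t in truth.items():
        if key not in voi_lookup:
            continue
        center, peak = voi_lookup[key]
        if t.n_foci > 0:
            center_err = float(min(np.linalg.norm(center - c) for c in t.focus_centers))
        else:
            center_err = np.nan
        pred = cls.loc[key]
        rows.append(
            {
                "subject": key[0], "muscle": key[1], "side": key[2],
                "true_pattern": t.pattern,
                "predicted_pattern": pred["subtype"] if pred["pattern"] == "heterogeneous" else "homogeneous",
                "pattern_correct": (
                    (t.pattern == "homogeneous" and pred["pattern"] == "homogeneous")
                    or (t.pattern != "homogeneous" and pred["subtype"] == t.pattern)
                ),
                "class_correct": (t.pattern == "homogeneous") == (pred["pattern"] == "homogeneous"),
                "center_error_mm": center_err,
                "suv_peak_error": float(peak - t.true_max_suv),
            }
        )
    return pd.DataFrame(rows)


def run_study(config: StudyConfig, atlas: MuscleAtlas | None = None) -> StudyReport:
    """Simulate, quantify, average, score, and compare — fully deterministic."""
    if atlas is None:
        atlas = generate_atlas(spacing=config.cohort.spacing_mm)
    phantoms, _truth_table = generate_cohort(config.cohort, atlas=atlas)

    tables = []
    all_vois: list[VOI] = []
    for ph in phantoms:
        t, v = quantify_phantom(
            ph,
            methods=config.methods,
            diameter_large_mm=config.diameter_large_mm,
            diameter_small_mm=config.diameter_small_mm,
            hotspot_params=config.hotspot,
            d_peak_mm=config.d_peak_mm,
        )
        tables.append(t)
        all_vois.extend(v)
    suv_table = pd.concat(tables, ignore_index=True)

    averaged, symmetry = average_lr(suv_table)
    method_comparison = compare_methods(averaged) if len(config.methods) == 2 else pd.DataFrame()
    pattern_scores = score_patterns(phantoms, config, suv_table)
    pattern_table = tabulate(
        pattern_scores[["group", "muscle", "side", "pattern"]], groups=GROUPS
    )

    group_tests: dict = {}
    hot_avg = averaged[averaged["method"] == "hotspot"]
    for muscle in MUSCLES:
        sub = hot_avg[hot_avg["muscle"] == muscle]
        groups = [sub[sub["group"] == g]["suv_peak"].to_numpy() for g in GROUPS]
        if any(g.size < 3 for g in groups):
            continue
        try:
            group_tests[muscle] = group_compare(groups, labels=GROUPS)
        except DegenerateInputError:
            continue

    recovery = recovery_summary(phantoms, suv_table, all_vois, pattern_scores)
    return StudyReport(
        suv_table=suv_table,
        symmetry=symmetry,
        averaged=averaged,
        pattern_scores=pattern_scores,
        pattern_table=pattern_table,
        method_comparison=method_comparison,
        group_tests=group_tests,
        recovery=recovery,
        vois=all_vois,
    )


def write_report(report: StudyReport, outdir, plots: bool = True) -> None:
    """Write the report tables as CSV (and the agreement plots) to ``outdir``."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.suv_table.to_csv(out / "suv_table.csv", index=False)
    report.symmetry.to_csv(out / "symmetry.csv", index=False)
    report.averaged.to_csv(out / "suv_averaged.csv", index=False)
    report.pattern_scores.to_csv(out / "pattern_scores.csv", index=False)
    report.pattern_table.counts.to_csv(out / "pattern_table.csv", index=False)
    report.method_comparison.to_csv(out / "method_comparison.csv", index=False)
    report.recovery.to_csv(out / "recovery.csv", index=False)
    gt_rows = []
    for muscle, res in report.group_tests.items():
        gt_rows.append(
            {"muscle": muscle, "test": res.test, "statistic": res.statistic, "p": res.p,
             "variance_p": res.gate.evidence.variance_p,
             "min_shapiro_p": min(res.gate.evidence.shapiro_p)}
        )
    pd.DataFrame(gt_rows).to_csv(out / "group_tests.csv", index=False)
    if plots and not report.method_comparison.empty:
        plot_bland_altman(report, out / "bland_altman.png")


def plot_bland_altman(report: StudyReport, path) -> None:
    """Bland–Altman scatter (pooled, fixed - hotspot) with bias and limits."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wide = report.averaged.pivot_table(
        index=["subject", "group", "muscle"], columns="method", values="suv_peak", aggfunc="first"
    ).reset_index().dropna(subset=["fixed", "hotspot"])
    d = wide["fixed"] - wide["hotspot"]
    m = (wide["fixed"] + wide["hotspot"]) / 2.0
    pooled = report.method_comparison[report.method_comparison["scope"] == "pooled"].iloc[0]
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(m, d, s=12, alpha=0.6)
    for y, style in ((pooled["bias"], "-"), (pooled["lower"], "--"), (pooled["upper"], "--")):
        ax.axhline(y, color="k", linestyle=style, linewidth=1)
    ax.axhline(0, color="gray", linewidth=0.5)
    ax.set_xlabel("mean of methods (SUV$_{peak}$)")
    ax.set_ylabel(r"$\Delta$SUV (fixed $-$ hotspot)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
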