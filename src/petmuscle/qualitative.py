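"""Automated analog of visual uptake scoring.

Two judgements are reproduced as deterministic statistics:

* **positivity** — a muscle is scored positive (1) when its SUV_peak is at
  least the mediastinal blood-pool reference uptake, else 0 (boundary
  inclusive).
* **pattern** — in-muscle heterogeneity is summarized by the coefficient of
  variation (CV = SD/mean) of the muscle's SUV values.  CV at or below a
  threshold (default 0.15) reads as homogeneous; above it, the number of
  26-connected components of voxels exceeding mean + z*SD (default z = 2)
  sets the subtype: one component = unifocal, two or more = multifocal, none
  (high CV without discrete foci) = diffuse.

This is a stand-in for visual scoring by blinded readers, not a validated
clinical classifier; thresholds are configuration values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import label as cc_label

from .suv import SUVStats, SUVVolume


class UndefinedCVError(ValueError):
    """Coefficient of variation undefined (zero-mean muscle uptake)."""


@dataclass(frozen=True)
class PatternScore:
    """Scored uptake pattern for one muscle compartment."""

    muscle: str
    side: str
    positivity: int  # 0/1 vs the blood-pool reference
    pattern: str  # "homogeneous" | "heterogeneous"
    subtype: str  # "unifocal" | "multifocal" | "diffuse" | "none"
    cv: float
    focus_count: int

    def __post_init__(self):
        if (self.pattern == "homogeneous") != (self.subtype == "none"):
            raise ValueError("subtype 'none' iff pattern homogeneous")


def positivity(stats: SUVStats, reference_suv: float) -> int:
    """1 iff SUV_peak >= reference (boundary inclusive), else 0."""
    if reference_suv <= 0:
        raise ValueError("reference SUV must be positive")
    return int(stats.suv_peak >= reference_suv)


_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


def classify_pattern(
    suv: SUVVolume,
    muscle_mask: np.ndarray,
    muscle: str = "",
    side: str = "",
    cv_threshold: float = 0.15,
    z: float = 2.0,
    positivity_score: int = 0,
) -> PatternScore:
    """Classify the uptake pattern of one muscle compartment."""
    vals = suv.values[muscle_mask]
    if vals.size == 0:
        raise ValueError(f"{muscle} {side}: empty muscle mask")
    mean = float(vals.mean())
    if mean <= 0:
        raise UndefinedCVError(f"{muscle} {side}: zero-mean uptake, CV undefined")
    sd = float(vals.std(ddof=0))
    cv = sd / mean
    if cv <= cv_threshold:
        return PatternScore(muscle, side, positivity_score, "homogeneous", "none", cv, 0)
    hot = np.zeros_like(muscle_mask)
    hot[muscle_mask] = suv.values[muscle_mask] > mean + z * sd
    _, n_comp = cc_label(hot, structure=_STRUCT26)
    if n_comp == 0:
        subtype = "diffuse"
    elif n_comp == 1:
        subtype = "unifocal"
    else:
        subtype = "multifocal"
    return PatternScore(muscle, side, positivity_score, "heterogeneous", subtype, cv, int(n_comp))


@dataclass
class PatternTable:
    """Pattern counts per group x muscle x side, plus a subset aggregate."""

    counts: pd.DataFrame  # columns: group, muscle, side, homogeneous, heterogeneous
    subset: tuple
    aggregate_heterogeneous_pct: int  # rounded to whole percent
    aggregate_heterogeneous: int
    aggregate_total: int

    def totals(self) -> pd.DataFrame:
        """Per muscle x side totals over all groups."""
        return (
            self.counts.groupby(["muscle", "side"], as_index=False)[["homogeneous", "heterogeneous"]]
            .sum()
        )


def tabulate(scores, groups, subset=("quadriceps", "hamstrings")) -> PatternTable:
    """Tabulate pattern scores per group x muscle x side.

    Parameters
    ----------
    scores
        Iterable of (group, PatternScore) pairs, or a DataFrame with columns
        group/muscle/side/pattern.  Missing compartments are simply absent
        (totals conserve the number of scored muscles).
    groups
        Group labels in display order.
    subset
        Muscle names aggregated into the headline heterogeneous fraction
        (left+right, all groups), reported as a whole-number percentage.
    """
    if len(subset) == 0:
        raise ValueError("subset must name at least one muscle")
    if isinstance(scores, pd.DataFrame):
        df = scores.copy()
    else:
        df = pd.DataFrame(
            [
                {"group": g, "muscle": s.muscle, "side": s.side, "pattern": s.pattern}
                for g, s in scores
            ]
        )
    if df.empty:
        raise ValueError("no scores to tabulate")
    df["heterogeneous"] = (df["pattern"] == "heterogeneous").astype(int)
    df["homogeneous"] = 1 - df["heterogeneous"]
    counts = (
        df.groupby(["group", "muscle", "side"], as_index=False)[["homogeneous", "heterogeneous"]]
        .sum()
    )
    counts["group"] = pd.Categorical(counts["group"], categories=list(groups), ordered=True)
    counts = counts.sort_values(["muscle", "side", "group"]).reset_index(drop=True)
    sub = df[df["muscle"].isin(subset)]
    het = int(sub["heterogeneous"].sum())
    total = int(len(sub))
    if total == 0:
        raise ValueError(f"no scored muscles in subset {subset}")
    pct = int(round(100.0 * het / total))
    return PatternTable(
        counts=counts,
        subset=tuple(subset),
        aggregate_heterogeneous_pct=pct,
        aggregate_heterogeneous=het,
        aggregate_total=total,
    )
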