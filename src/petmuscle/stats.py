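"""The statistical battery used for method and group comparison.

Covers left/right symmetry (paired t), method agreement (Pearson/Spearman
correlation and Bland–Altman limits of agreement), a normality/homoscedasticity
gate (Shapiro–Wilk + variance-ratio F test) selecting ANOVA vs Kruskal–Wallis,
and Dunn's rank-based post-hoc test with Bonferroni adjustment.  Standard
tests delegate to :mod:`scipy.stats`; Dunn's test and the Bland–Altman
construction are implemented here.  All p-values are two-sided and the
significance convention is alpha = 0.05 with stars * p<0.05, ** p<0.01,
*** p<0.001.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats as sps

ALPHA = 0.05


class DegenerateInputError(ValueError):
    """Input has no variability where the test requires some."""


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# --------------------------------------------------------------------------
# paired comparison and correlation


@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    mean_diff: float
    n: int


def paired_t(x, y) -> PairedTResult:
    """Classical two-sided paired t test on d = x - y (n-1 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    if np.allclose(d.std(ddof=1), 0.0):
        raise DegenerateInputError("zero-variance differences")
    t, p = sps.ttest_rel(x, y)
    return PairedTResult(t=float(t), p=float(p), mean_diff=float(d.mean()), n=int(x.size))


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # "pearson" | "spearman"
    r: float
    r2: float
    p: float
    n: int


def correlation(x, y, method: str = "pearson") -> CorrelationResult:
    """Pearson correlation on values or Spearman on average ranks; R^2 = r^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.allclose(x.std(), 0.0) or np.allclose(y.std(), 0.0):
        raise DegenerateInputError("zero variance in x or y")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(method=method, r=float(r), r2=float(r) ** 2, p=float(p), n=int(x.size))


# --------------------------------------------------------------------------
# Bland–Altman


@dataclass(frozen=True)
class BlandAltmanResult:
    """Agreement of two paired measurements: bias and 95% limits.

    ``bias`` is the mean difference (first minus second), the limits are
    bias +- 1.96 SD of the differences, expected to bracket ~95% of pairs.
    """

    bias: float
    sd: float
    lower: float
    upper: float
    n: int

    @property
    def differences_width(self) -> float:
        return self.upper - self.lower  # identically 2 * 1.96 * sd


def bland_altman(a, b) -> BlandAltmanResult:
    """Bland–Altman analysis of differences d = a - b against means (a+b)/2."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, sd=sd, lower=bias - 1.96 * sd, upper=bias + 1.96 * sd, n=int(a.size))


def bland_altman_lower_from_bias_upper(bias: float, upper: float) -> float:
    """Lower limit implied by the symmetric construction: lower = 2*bias - upper."""
    return 2.0 * bias - upper


# --------------------------------------------------------------------------
# normality gate and omnibus tests


@dataclass(frozen=True)
class GateEvidence:
    shapiro_p: tuple  # per group
    variance_p: float
    variance_test: str


@dataclass(frozen=True)
class GateDecision:
    choice: str  # "anova" | "kruskal-wallis"
    evidence: GateEvidence


def _variance_ratio_p(groups) -> float:
    """Two-sided variance-ratio F test; for >2 groups the max-ratio pair."""
    best = None
    for gi, gj in combinations(range(len(groups)), 2):
        vi = np.var(groups[gi], ddof=1)
        vj = np.var(groups[gj], ddof=1)
        if vj == 0 and vi == 0:
            continue
        if vj == 0 or (vj > 0 and vi / vj < 1):
            gi, gj = gj, gi
            vi, vj = vj, vi
        if vj == 0:
            return 0.0
        f = vi / vj
        if best is None or f > best[0]:
            best = (f, len(groups[gi]) - 1, len(groups[gj]) - 1)
    if best is None:
        raise DegenerateInputError("all groups have zero variance")
    f, dfn, dfd = best
    return float(min(1.0, 2.0 * sps.f.sf(f, dfn, dfd)))


def normality_gate(groups, alpha: float = ALPHA, variance_test: str = "f") -> GateDecision:
    """Choose ANOVA vs Kruskal–Wallis.

    ANOVA iff every group passes Shapiro–Wilk (p >= alpha) AND the variance
    homogeneity test passes (p >= alpha); otherwise Kruskal–Wallis.
    ``variance_test`` is the classical variance-ratio F test (``"f"``,
    max-ratio pair for >2 groups) or Levene's test (``"levene"``).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for g in groups:
        if g.size < 3:
            raise ValueError("each group needs n >= 3")
    shapiro_p = tuple(float(sps.shapiro(g).pvalue) for g in groups)
    if variance_test == "f":
        var_p = _variance_ratio_p(groups)
    elif variance_test == "levene":
        var_p = float(sps.levene(*groups).pvalue)
    else:
        raise ValueError(f"unknown variance test {variance_test!r}")
    choice = "anova" if (min(shapiro_p) >= alpha and var_p >= alpha) else "kruskal-wallis"
    return GateDecision(choice=choice, evidence=GateEvidence(shapiro_p, var_p, variance_test))


def one_way_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if all(np.var(g) == 0 for g in groups):
        raise DegenerateInputError("zero within-group variance everywhere")
    f, p = sps.f_oneway(*groups)
    return float(f), float(p)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H; p from chi-square with (k-1) df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if sum(g.size for g in groups) < 4:
        raise ValueError("need total n >= 4")
    if np.unique(np.concatenate(groups)).size < 2:
        raise DegenerateInputError("all values identical; ranks carry no information")
    try:
        h, p = sps.kruskal(*groups)
    except ValueError as exc:  # scipy raises when all values are identical
        raise DegenerateInputError(str(exc)) from exc
    return float(h), float(p)


# --------------------------------------------------------------------------
# Dunn's post-hoc test


@dataclass(frozen=True)
class DunnPair:
    i: int
    j: int
    z: float
    p_raw: float
    p_adj: float


def dunn_posthoc(groups, adjustment: str = "bonferroni") -> list[DunnPair]:
    """Dunn's pairwise mean-rank comparison after a Kruskal–Wallis omnibus.

    z_ij = (rbar_i - rbar_j) / sqrt[(N(N+1)/12 - T)(1/n_i + 1/n_j)] with the
    tie correction T = sum(t^3 - t) / (12 (N - 1)).  Raw two-sided p from the
    normal distribution; ``bonferroni`` multiplies by the number of pairs
    (capped at 1), ``none`` leaves it unadjusted.
    """
    if adjustment not in ("bonferroni", "none"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    ranks = sps.rankdata(pooled)  # average ranks for ties
    mean_ranks = []
    start = 0
    for g in groups:
        mean_ranks.append(ranks[start : start + g.size].mean())
        start += g.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_core = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(groups) * (len(groups) - 1) // 2
    out = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_core * (1.0 / groups[i].size + 1.0 / groups[j].size))
        if se == 0:
            raise DegenerateInputError("zero rank variance (all values identical)")
        z = (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        p_adj = min(1.0, m * p_raw) if adjustment == "bonferroni" else p_raw
        out.append(DunnPair(i=i, j=j, z=float(z), p_raw=p_raw, p_adj=p_adj))
    return out


# --------------------------------------------------------------------------
# combined group comparison


@dataclass(frozen=True)
class GroupTestResult:
    """Gated omnibus comparison with Dunn post-hoc pairs."""

    test: str  # "anova" | "kruskal-wallis"
    statistic: float  # F or H
    p: float
    gate: GateDecision
    pairwise: list = field(default_factory=list)
    group_labels: tuple = ()


def group_compare(groups, labels=None, alpha: float = ALPHA, variance_test: str = "f") -> GroupTestResult:
    """Run the gate, the chosen omnibus test, and Dunn's post-hoc."""
    gate = normality_gate(groups, alpha=alpha, variance_test=variance_test)
    if gate.choice == "anova":
        stat, p = one_way_anova(groups)
    else:
        stat, p = kruskal_wallis(groups)
    pairwise = dunn_posthoc(groups)
    return GroupTestResult(
        test=gate.choice,
        statistic=stat,
        p=p,
        gate=gate,
        pairwise=pairwise,
        group_labels=tuple(labels) if labels is not None else tuple(range(len(groups))),
    )
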