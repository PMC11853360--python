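"""Statistical battery vs hand-computed and simulation oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from petmuscle import (
    DegenerateInputError,
    bland_altman,
    bland_altman_lower_from_bias_upper,
    correlation,
    dunn_posthoc,
    group_compare,
    kruskal_wallis,
    normality_gate,
    one_way_anova,
    paired_t,
    significance_stars,
)


class TestPairedT:
    def test_symmetric_differences_give_t_zero_p_one(self):
        res = paired_t([2, 0, 2, 0], [1, 1, 1, 1])
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)
        assert res.mean_diff == pytest.approx(0.0)

    def test_location_shift_recovers_mean_difference(self):
        rng = np.random.default_rng(0)
        y = rng.normal(0, 0.5, 500)
        res = paired_t(y + 1.0, y + rng.normal(0, 1e-6, 500))
        assert res.mean_diff == pytest.approx(1.0, abs=1e-5)

    def test_hand_computed_example(self):
        # d = (0.1, 0.3, 0.2): dbar = 0.2, s_d = 0.1, t = 0.2/(0.1/sqrt(3)) = 2*sqrt(3)
        res = paired_t([0.1, 0.3, 0.2], [0.0, 0.0, 0.0])
        assert res.t == pytest.approx(2 * np.sqrt(3.0), rel=1e-9)
        assert res.p == pytest.approx(0.074180, abs=1e-5)

    def test_zero_variance_differences_rejected(self):
        with pytest.raises(DegenerateInputError):
            paired_t([1, 2, 3], [0, 1, 2])


class TestCorrelation:
    def test_proportional_data_pearson_one(self):
        res = correlation([1, 2, 3, 4], [2, 4, 6, 8], "pearson")
        assert res.r == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_monotone_decreasing_spearman_minus_one(self):
        x = np.array([1.0, 2.0, 5.0, 9.0])
        res = correlation(x, np.exp(-x), "spearman")
        assert res.r == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        # x=(1,2,3), y=(1,2,4): r = 3/sqrt(2*14/3) ~ 0.981981
        res = correlation([1, 2, 3], [1, 2, 4], "pearson")
        assert res.r == pytest.approx(3.0 / np.sqrt(2 * 14 / 3), rel=1e-9)
        assert res.r2 == pytest.approx(res.r**2)

    def test_affine_invariance_of_pearson_and_monotone_invariance_of_spearman(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=30)
        y = x + rng.normal(scale=0.3, size=30)
        r0 = correlation(x, y, "pearson").r
        assert correlation(3.0 * x - 2.0, 0.5 * y + 7.0, "pearson").r == pytest.approx(r0)
        s0 = correlation(x, y, "spearman").r
        assert correlation(x, np.exp(y), "spearman").r == pytest.approx(s0)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            correlation([1, 1, 1], [1, 2, 3])


class TestBlandAltman:
    def test_identical_methods(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == res.sd == res.lower == res.upper == 0.0

    def test_constant_offset(self):
        res = bland_altman([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert res.bias == pytest.approx(1.0)
        assert res.sd == pytest.approx(0.0)
        assert res.lower == res.upper == pytest.approx(1.0)

    def test_reported_limits_internally_consistent(self):
        # bias -0.147 with upper limit 0.117 implies lower limit -0.411
        assert bland_altman_lower_from_bias_upper(-0.147, 0.117) == pytest.approx(-0.411)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10, 10), min_size=2, max_size=30), st.integers(0, 10**6))
    def test_limit_identity_on_random_pairs(self, a, seed):
        rng = np.random.default_rng(seed)
        a = np.asarray(a)
        b = a + rng.normal(size=a.size)
        res = bland_altman(a, b)
        assert res.upper - res.lower == pytest.approx(2 * 1.96 * res.sd, rel=1e-9, abs=1e-9)
        assert res.lower == pytest.approx(2 * res.bias - res.upper, rel=1e-9, abs=1e-9)


class TestNormalityGate:
    def test_normal_equal_variance_data_chooses_anova(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            g = [rng.normal(0, 1, 50), rng.normal(0, 1, 50)]
            hits += normality_gate(g).choice == "anova"
        assert hits >= 90

    def test_skewed_group_forces_kruskal_wallis(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            g = [np.exp(rng.normal(0, 1, 50)), rng.normal(0, 1, 50)]
            hits += normality_gate(g).choice == "kruskal-wallis"
        assert hits >= 90

    def test_location_shift_does_not_change_decision(self):
        rng = np.random.default_rng(3)
        g1 = rng.normal(0, 1, 40)
        g2 = rng.normal(0, 1, 40)
        d0 = normality_gate([g1, g2])
        d1 = normality_gate([g1 + 100.0, g2 - 50.0])
        assert d0.choice == d1.choice
        assert d0.evidence.variance_p == pytest.approx(d1.evidence.variance_p)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            normality_gate([[1.0, 2.0], [1.0, 2.0, 3.0]])

    def test_levene_alternative_available(self):
        rng = np.random.default_rng(4)
        g = [rng.normal(0, 1, 30), rng.normal(0, 3, 30)]
        assert normality_gate(g, variance_test="levene").choice == "kruskal-wallis"


class TestKruskalWallis:
    def test_hand_computed_h_without_ties(self):
        # groups {1,2} and {3,4}: H = 12/(4*5) * (2*1.5^2 + 2*3.5^2) - 3*5 = 2.4
        h, _ = kruskal_wallis([[1.0, 2.0], [3.0, 4.0]])
        assert h == pytest.approx(2.4, rel=1e-12)

    def test_rank_based_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(5)
        g = [rng.normal(0, 1, 12), rng.normal(0.5, 1, 10), rng.normal(1, 1, 11)]
        h0, p0 = kruskal_wallis(g)
        h1, p1 = kruskal_wallis([np.exp(x) for x in g])
        assert h1 == pytest.approx(h0)
        assert p1 == pytest.approx(p0)

    def test_identical_values_rejected(self):
        with pytest.raises(DegenerateInputError):
            kruskal_wallis([[1.0, 1.0], [1.0, 1.0]])


class TestDunn:
    def test_identical_groups_give_z_zero_p_one(self):
        pairs = dunn_posthoc([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert pairs[0].z == pytest.approx(0.0)
        assert pairs[0].p_raw == pytest.approx(1.0)

    def test_bonferroni_multiplies_by_pair_count(self):
        groups = [[1.0, 2.0], [2.5, 3.5], [5.0, 6.0]]
        pairs = dunn_posthoc(groups, adjustment="bonferroni")
        raw = dunn_posthoc(groups, adjustment="none")
        assert len(pairs) == 3
        for p, r in zip(pairs, raw):
            assert p.p_adj == pytest.approx(min(1.0, 3 * r.p_raw))

    def test_hand_computed_z_without_ties(self):
        # {1,2},{3,4},{5,6}: mean ranks 1.5/3.5/5.5, var core N(N+1)/12 = 3.5,
        # z(1,3) = (1.5-5.5)/sqrt(3.5*(1/2+1/2)) = -4/sqrt(3.5)
        pairs = {(p.i, p.j): p for p in dunn_posthoc([[1, 2], [3, 4], [5, 6]])}
        assert pairs[(0, 2)].z == pytest.approx(-4.0 / np.sqrt(3.5), rel=1e-12)
        assert pairs[(0, 1)].z == pytest.approx(-2.0 / np.sqrt(3.5), rel=1e-12)

    def test_hand_computed_z_with_ties(self):
        # pooled (1,1,1,2): ranks (2,2,2,4); tie term (3^3-3)/(12*3) = 2/3;
        # var core = 4*5/12 - 2/3 = 1; z = (2-3)/sqrt(1*(1/2+1/2)) = -1
        pairs = dunn_posthoc([[1.0, 1.0], [1.0, 2.0]])
        assert pairs[0].z == pytest.approx(-1.0, rel=1e-12)


class TestAnova:
    def test_equal_group_means_give_f_zero(self):
        f, p = one_way_anova([[1.0, 3.0], [1.9, 2.1]])
        assert f == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_two_groups_f_equals_squared_t(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 15), rng.normal(0.8, 1, 12)
        f, p_f = one_way_anova([a, b])
        from scipy.stats import ttest_ind

        t, p_t = ttest_ind(a, b)
        assert f == pytest.approx(t**2, rel=1e-10)
        assert p_f == pytest.approx(p_t, rel=1e-10)

    def test_hand_computed_f(self):
        # {1,2} vs {5,6}: MSB = 2*(2^2)*... = 16, MSW = 0.5, F = 32
        f, _ = one_way_anova([[1.0, 2.0], [5.0, 6.0]])
        assert f == pytest.approx(32.0, rel=1e-12)

    def test_all_constant_rejected(self):
        with pytest.raises(DegenerateInputError):
            one_way_anova([[2.0, 2.0], [2.0, 2.0]])


def test_group_compare_combines_gate_omnibus_and_posthoc():
    rng = np.random.default_rng(7)
    groups = [rng.normal(m, 1, 12) for m in (0.0, 0.2, 1.5)]
    res = group_compare(groups, labels=("a", "b", "c"))
    assert res.test in ("anova", "kruskal-wallis")
    assert len(res.pairwise) == 3
    assert all(p.p_adj >= p.p_raw for p in res.pairwise)
    assert res.group_labels == ("a", "b", "c")


@pytest.mark.parametrize(
    "p, stars", [(0.04, "*"), (0.004, "**"), (0.0004, "***"), (0.2, "ns"), (0.05, "ns")]
)
def test_significance_star_convention(p, stars):
    assert significance_stars(p) == stars
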