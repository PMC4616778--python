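"""Group comparisons, mixed ANOVA, ROC/Youden/DeLong, and sample size."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dynea import cohort_stats as cs


# --------------------------------------------------------------------------
# compare_groups
# --------------------------------------------------------------------------

class TestCompareGroups:
    def test_normal_data_uses_t_test(self):
        rng = np.random.default_rng(0)
        x = np.r_[rng.normal(0.61, 0.1, 22), rng.normal(0.79, 0.1, 17)]
        labels = np.r_[np.zeros(22), np.ones(17)]
        res = cs.compare_groups(x, labels, "continuous", variable="ea")
        assert res.test_used == "t_test"
        assert all(p >= 0.05 for p in res.normality_p)

    def test_skewed_data_uses_mann_whitney(self):
        rng = np.random.default_rng(1)
        x = np.r_[rng.lognormal(0, 1.5, 30), rng.lognormal(0.5, 1.5, 30)]
        labels = np.r_[np.zeros(30), np.ones(30)]
        res = cs.compare_groups(x, labels, "continuous")
        assert res.test_used == "mann_whitney"

    def test_identical_groups_no_difference(self):
        x = np.r_[np.arange(10.0), np.arange(10.0)]
        labels = np.r_[np.zeros(10), np.ones(10)]
        res = cs.compare_groups(x, labels, "continuous")
        assert res.statistic == pytest.approx(0.0, abs=1e-12) \
            or res.p_value > 0.9

    def test_sparse_categorical_uses_fisher(self):
        values = ["yes"] * 3 + ["no"] * 7 + ["yes"] * 1 + ["no"] * 9
        labels = [0] * 10 + [1] * 10
        res = cs.compare_groups(np.array(values), np.array(labels),
                                "categorical")
        assert res.test_used == "fisher_exact"

    def test_dense_categorical_uses_chi_square(self):
        values = ["yes"] * 15 + ["no"] * 15 + ["yes"] * 8 + ["no"] * 22
        labels = [0] * 30 + [1] * 30
        res = cs.compare_groups(np.array(values), np.array(labels),
                                "categorical")
        assert res.test_used == "chi_square"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="3 patients"):
            cs.compare_groups(np.arange(5.0), np.array([0, 0, 1, 1, 1]),
                              "continuous")

    def test_separated_groups_significant_in_simulation(self):
        """0.79 vs 0.61 with small sd is detected in >=95% of 1000 trials."""
        rng = np.random.default_rng(5)
        hits = 0
        for _ in range(1000):
            x = np.r_[rng.normal(0.79, 0.05, 17), rng.normal(0.61, 0.05, 22)]
            labels = np.r_[np.ones(17), np.zeros(22)]
            hits += cs.compare_groups(x, labels, "continuous").p_value < 0.05
        assert hits >= 950


# --------------------------------------------------------------------------
# Fisher exact: exhaustive hypergeometric oracle
# --------------------------------------------------------------------------

def fisher_two_sided_oracle(a, b, c, d):
    """Exact two-sided Fisher p by integer hypergeometric enumeration."""
    r1, r2 = a + b, c + d
    c1, n = a + c, a + b + c + d
    denom = math.comb(n, c1)
    pmf_obs = Fraction(math.comb(r1, a) * math.comb(r2, c1 - a), denom)
    p = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)
        if px <= pmf_obs:
            p += px
    return float(p)


def test_fisher_matches_enumeration_on_spec_table():
    # perfectly concordant 10/0 vs 0/10 table: p = 2 / C(20, 10)
    _, p = stats.fisher_exact([[10, 0], [0, 10]])
    assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)
    assert p == pytest.approx(fisher_two_sided_oracle(10, 0, 0, 10), rel=1e-12)


# --------------------------------------------------------------------------
# rm_anova_two_way
# --------------------------------------------------------------------------

def toy_mixed_design():
    rows = []
    data = {("A", "s1"): (1.0, 3.0), ("A", "s2"): (2.0, 6.0),
            ("B", "s3"): (4.0, 8.0), ("B", "s4"): (5.0, 11.0)}
    for (g, s), (v1, v2) in data.items():
        rows += [{"subject": s, "group": g, "time": "t1", "value": v1},
                 {"subject": s, "group": g, "time": "t2", "value": v2}]
    return pd.DataFrame(rows)


class TestRmAnova:
    def test_matches_hand_computed_sums_of_squares(self):
        # frozen from a pencil-and-paper decomposition of the 8-cell table:
        # SS_total=76, SS_between_subj=40, SS_group=32 (so SS_subj=8, df 2),
        # SS_time=32, SS_inter=2, SS_err=76-40-32-2=2 (df 2);
        # F_group=(32/1)/(8/2)=8, F_time=(32/1)/(2/2)=32, F_inter=2
        res = toy_mixed_design().pipe(cs.rm_anova_two_way).set_index("effect")
        assert res.loc["group", "F"] == pytest.approx(8.0, abs=1e-12)
        assert res.loc["time", "F"] == pytest.approx(32.0, abs=1e-12)
        assert res.loc["group:time", "F"] == pytest.approx(2.0, abs=1e-12)

    def test_all_identical_values_give_zero_f(self):
        df = toy_mixed_design().assign(value=5.0)
        res = cs.rm_anova_two_way(df)
        assert (res["F"] == 0.0).all() and (res["p"] == 1.0).all()

    def test_pure_group_offset_zero_noise(self):
        df = toy_mixed_design()
        df["value"] = np.where(df["group"] == "A", 5.0, 8.0)
        res = cs.rm_anova_two_way(df).set_index("effect")
        assert np.isinf(res.loc["group", "F"])
        assert res.loc["group", "p"] == 0.0
        assert res.loc["time", "F"] == 0.0

    def test_missing_timepoint_raises(self):
        df = toy_mixed_design().iloc[:-1]
        with pytest.raises(ValueError, match="missing"):
            cs.rm_anova_two_way(df)

    def test_matches_pingouin_on_random_design(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(0)
        rows = []
        for i in range(12):
            g = "A" if i < 5 else "B"
            base = rng.normal(70, 5)
            for t in ["T1", "T2", "T3", "T4"]:
                bump = 3.0 if (g == "B" and t in ("T3", "T4")) else 0.0
                rows.append({"subject": f"s{i}", "group": g, "time": t,
                             "value": base + rng.normal(0, 3) + bump})
        df = pd.DataFrame(rows)
        mine = cs.rm_anova_two_way(df).set_index("effect")
        ref = pg.mixed_anova(data=df, dv="value", within="time",
                             subject="subject", between="group")
        ref = ref.set_index("Source")
        for eff, src in [("group", "group"), ("time", "time"),
                         ("group:time", "Interaction")]:
            assert mine.loc[eff, "F"] == pytest.approx(ref.loc[src, "F"],
                                                       rel=1e-9)
            assert mine.loc[eff, "p"] == pytest.approx(ref.loc[src, "p_unc"],
                                                       rel=1e-9)

    def test_null_group_pvalues_uniform(self):
        """Under a null with no group effect the group p-value is U(0,1)."""
        rng = np.random.default_rng(123)
        pvals = []
        for _ in range(500):
            rows = []
            for i in range(10):
                g = "A" if i < 5 else "B"
                base = rng.normal(0, 1)
                for t in range(4):
                    rows.append({"subject": i, "group": g, "time": t,
                                 "value": base + rng.normal(0, 1)})
            res = cs.rm_anova_two_way(pd.DataFrame(rows)).set_index("effect")
            pvals.append(res.loc["group", "p"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


# --------------------------------------------------------------------------
# ROC / Youden / DeLong
# --------------------------------------------------------------------------

class TestRoc:
    def test_perfect_separation(self):
        r = cs.roc_analysis([0.6, 0.61, 0.8, 0.9], [0, 0, 1, 1])
        assert r.auc == 1.0
        assert r.auc_ci_95[1] == 1.0
        assert r.youden_j == pytest.approx(1.0)
        assert 0.61 <= r.youden_cutoff < 0.8

    def test_all_tied_scores(self):
        r = cs.roc_analysis([5.0] * 8, [0, 1] * 4)
        assert r.auc == pytest.approx(0.5, abs=1e-12)
        assert r.youden_j == pytest.approx(0.0, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError, match="degenerate labels"):
            cs.roc_analysis([1.0, 2.0, 3.0], [1, 1, 1])

    def test_sensitivity_specificity_monotone(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(size=40)
        labels = rng.integers(0, 2, size=40)
        if labels.sum() < 2 or labels.sum() > 38:
            labels[:2] = [0, 1]
        r = cs.roc_analysis(scores, labels)
        assert np.all(np.diff(r.sensitivity) <= 1e-15)
        assert np.all(np.diff(r.specificity) >= -1e-15)

    def test_cutoff_table_reproduces_youden(self):
        rng = np.random.default_rng(3)
        scores = np.round(rng.normal(size=30), 1)
        labels = np.r_[np.ones(12, int), np.zeros(18, int)]
        r = cs.roc_analysis(scores, labels)
        tab = r.cutoff_table
        best = tab.loc[tab["youden_j"].idxmax()]
        assert best["cutoff"] == r.youden_cutoff
        assert best["youden_j"] == pytest.approx(r.youden_j)

    def test_curve_trapezoid_equals_auc(self):
        rng = np.random.default_rng(4)
        scores = np.round(rng.normal(size=25), 1)
        labels = np.r_[np.ones(10, int), np.zeros(15, int)]
        r = cs.roc_analysis(scores, labels)
        fpr, tpr = r.curve_points()
        assert np.trapezoid(tpr, fpr) == pytest.approx(r.auc, abs=1e-12)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.data())
    def test_auc_equals_mann_whitney(self, data):
        n1 = data.draw(st.integers(2, 8))
        n0 = data.draw(st.integers(2, 8))
        vals = data.draw(st.lists(
            st.integers(0, 5), min_size=n1 + n0, max_size=n1 + n0))
        scores = np.array(vals, dtype=float)
        labels = np.r_[np.ones(n1, int), np.zeros(n0, int)]
        r = cs.roc_analysis(scores, labels)
        u = stats.mannwhitneyu(scores[:n1], scores[n1:],
                               alternative="two-sided").statistic
        assert r.auc == pytest.approx(u / (n1 * n0), abs=1e-12)


# --------------------------------------------------------------------------
# Sample size
# --------------------------------------------------------------------------

class TestSampleSize:
    def test_shrinks_with_effect_size(self):
        n = [cs.sample_size_auc(cs.SampleSizeSpec(auc_alt=a)).n_total
             for a in (0.65, 0.75, 0.85, 0.95)]
        assert n == sorted(n, reverse=True)

    def test_grows_with_stricter_alpha(self):
        n_loose = cs.sample_size_auc(cs.SampleSizeSpec(alpha=0.05)).n_total
        n_strict = cs.sample_size_auc(cs.SampleSizeSpec(alpha=0.01)).n_total
        assert n_strict >= n_loose

    def test_exact_variant_is_conservative(self):
        n_hm = cs.sample_size_auc(cs.SampleSizeSpec()).n_total
        n_exact = cs.sample_size_auc(cs.SampleSizeSpec(variant="exact")).n_total
        assert n_exact >= n_hm

    def test_enrollment_inflation_rounds_to_nearest(self):
        spec = cs.sample_size_auc(cs.SampleSizeSpec())
        assert spec.n_enrolled == round(spec.n_total * 1.1)

    def test_unreachable_power_raises(self):
        with pytest.raises(ValueError, match="unreachable"):
            cs.sample_size_auc(cs.SampleSizeSpec(auc_null=0.75, auc_alt=0.75))
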