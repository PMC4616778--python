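"""Cohort-level statistics for arterial-pressure responsiveness studies.

Implements the statistical plan of a two-group (responder vs nonresponder)
fluid-challenge study:

* normality-gated two-group comparison (Shapiro-Wilk -> unpaired t test or
  Mann-Whitney; chi-square or Fisher's exact for categorical data),
* two-way repeated-measures ANOVA (group x time, subjects nested in group,
  classical sums of squares, no sphericity correction),
* empirical ROC analysis with the trapezoid/Mann-Whitney AUC, a DeLong 95%
  confidence interval, the Youden optimal cut-off, and the full
  cut-off/sensitivity/specificity table,
* AUC-based sample-size computation (Hanley-McNeil).

The ROC orientation is fixed: higher scores predict responders (auto-flipping
is deliberately disabled so a sign error cannot hide behind an inverted
curve).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupComparison",
    "RocResult",
    "SampleSizeSpec",
    "compare_groups",
    "rm_anova_two_way",
    "roc_analysis",
    "youden_optimal_cutoff",
    "sample_size_auc",
]

NORMALITY_ALPHA = 0.05
EXPECTED_COUNT_MIN = 5.0


# --------------------------------------------------------------------------
# Two-group comparison with normality-gated test selection
# --------------------------------------------------------------------------

@dataclass
class GroupComparison:
    variable: str
    test_used: str  # t_test | mann_whitney | chi_square | fisher_exact
    statistic: float
    p_value: float
    normality_p: tuple[float, float] | None = None
    group_summary: pd.DataFrame | None = None


def compare_groups(values, labels, variable_kind: str = "continuous",
                   variable: str = "") -> GroupComparison:
    """Compare a variable between two groups with the protocol's test gate.

    Continuous data: Shapiro-Wilk per group; unpaired Student t test when
    both groups are compatible with normality (p >= 0.05), Mann-Whitney rank
    sum otherwise.  Categorical data: chi-square, or Fisher's exact test when
    any expected cell count is below 5 (2x2 tables).  All p-values two-sided.
    """
    values = np.asarray(values)
    labels = np.asarray(labels)
    if values.shape != labels.shape:
        raise ValueError("values and labels must have the same length")
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {len(groups)}")
    g0 = values[labels == groups[0]]
    g1 = values[labels == groups[1]]
    if len(g0) == 0 or len(g1) == 0:
        raise ValueError("one group is empty")

    if variable_kind == "continuous":
        if len(g0) < 3 or len(g1) < 3:
            raise ValueError("need >= 3 patients per group for continuous data")
        x0, x1 = g0.astype(float), g1.astype(float)
        p_norm0 = float(stats.shapiro(x0).pvalue)
        p_norm1 = float(stats.shapiro(x1).pvalue)
        summary = pd.DataFrame({
            "group": groups, "n": [len(x0), len(x1)],
            "mean": [x0.mean(), x1.mean()], "sd": [x0.std(ddof=1), x1.std(ddof=1)],
            "median": [np.median(x0), np.median(x1)],
        })
        if p_norm0 >= NORMALITY_ALPHA and p_norm1 >= NORMALITY_ALPHA:
            res = stats.ttest_ind(x0, x1, equal_var=True)
            test = "t_test"
        else:
            res = stats.mannwhitneyu(x0, x1, alternative="two-sided")
            test = "mann_whitney"
        return GroupComparison(variable=variable, test_used=test,
                               statistic=float(res.statistic),
                               p_value=float(res.pvalue),
                               normality_p=(p_norm0, p_norm1),
                               group_summary=summary)

    if variable_kind == "categorical":
        table = pd.crosstab(pd.Series(values, name="value"),
                            pd.Series(labels, name="group")).to_numpy()
        expected = stats.contingency.expected_freq(table)
        if (expected < EXPECTED_COUNT_MIN).any():
            if table.shape != (2, 2):
                raise ValueError(
                    "expected count < 5 in a non-2x2 table; Fisher's exact "
                    "test is only implemented for 2x2"
                )
            odds, p = stats.fisher_exact(table, alternative="two-sided")
            return GroupComparison(variable=variable, test_used="fisher_exact",
                                   statistic=float(odds), p_value=float(p))
        chi2, p, _, _ = stats.chi2_contingency(table)
        return GroupComparison(variable=variable, test_used="chi_square",
                               statistic=float(chi2), p_value=float(p))

    raise ValueError(f"unknown variable_kind {variable_kind!r}")


# --------------------------------------------------------------------------
# Two-way repeated-measures ANOVA (mixed design)
# --------------------------------------------------------------------------

def rm_anova_two_way(data: pd.DataFrame, value: str = "value",
                     subject: str = "subject", group: str = "group",
                     time: str = "time") -> pd.DataFrame:
    """Mixed two-way ANOVA: between factor ``group``, within factor ``time``.

    Classical sums-of-squares decomposition with subjects nested in group and
    no sphericity correction.  Every subject must have every time point (no
    imputation).  Returns one row per effect (group, time, interaction) with
    SS, df, F and p.  Zero-variance degenerate inputs follow the conventions
    F = 0 when the effect SS is zero and F = inf (p = 0) when the error mean
    square vanishes but the effect does not.
    """
    d = data[[subject, group, time, value]].dropna()
    times = np.sort(d[time].unique())
    b = len(times)
    counts = d.groupby(subject)[time].nunique()
    if (counts != b).any() or len(d) != len(d[[subject, time]].drop_duplicates()):
        bad = counts[counts != b].index.tolist()
        raise ValueError(f"missing or duplicated time points for subjects {bad}")
    subj_group = d.groupby(subject)[group].agg(lambda s: s.iloc[0])
    groups = np.sort(subj_group.unique())
    a = len(groups)
    if a < 2:
        raise ValueError("need at least 2 groups")
    if (subj_group.value_counts() < 2).any():
        raise ValueError("need at least 2 subjects per group")

    y = d[value].to_numpy(dtype=float)
    grand = y.mean()
    n_subj = len(subj_group)
    n_g = subj_group.value_counts()

    subj_means = d.groupby(subject)[value].mean()
    group_means = d.groupby(group)[value].mean()
    time_means = d.groupby(time)[value].mean()
    cell_means = d.groupby([group, time])[value].mean()

    ss_total = float(((y - grand) ** 2).sum())
    ss_between_subj = float(b * ((subj_means - grand) ** 2).sum())
    ss_group = float(b * sum(n_g[g] * (group_means[g] - grand) ** 2
                             for g in groups))
    ss_subj_within = ss_between_subj - ss_group
    ss_time = float(n_subj * ((time_means - grand) ** 2).sum())
    ss_inter = float(sum(n_g[g] * (cell_means[(g, t)] - group_means[g]
                                   - time_means[t] + grand) ** 2
                         for g in groups for t in times))
    ss_err_within = ss_total - ss_between_subj - ss_time - ss_inter

    df_group, df_subj = a - 1, n_subj - a
    df_time = b - 1
    df_inter = (a - 1) * (b - 1)
    df_err = (n_subj - a) * (b - 1)

    def f_and_p(ss_eff, df_eff, ss_err, df_err):
        tol = 1e-12 * max(ss_total, 1.0)
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err if df_err > 0 else 0.0
        if ss_eff <= tol:
            return 0.0, 1.0
        if ms_err <= tol:
            return float("inf"), 0.0
        f = ms_eff / ms_err
        return f, float(stats.f.sf(f, df_eff, df_err))

    rows = []
    for name, ss_eff, df_eff, ss_e, df_e in [
        ("group", ss_group, df_group, ss_subj_within, df_subj),
        ("time", ss_time, df_time, ss_err_within, df_err),
        ("group:time", ss_inter, df_inter, ss_err_within, df_err),
    ]:
        f, p = f_and_p(ss_eff, df_eff, ss_e, df_e)
        rows.append({"effect": name, "ss": ss_eff, "df1": df_eff,
                     "df2": df_e, "F": f, "p": p})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# ROC analysis
# --------------------------------------------------------------------------

@dataclass
class RocResult:
    """Empirical ROC curve with DeLong CI, Youden cut-off and cut-off table.

    ``thresholds`` are the ascending distinct score values; the positive
    prediction rule is ``score > cutoff``.  ``auc`` is the trapezoidal area,
    identical to the normalized Mann-Whitney U statistic with ties counted
    one half.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray  # P(score > t | positive), per threshold
    specificity: np.ndarray  # P(score <= t | negative), per threshold
    auc: float
    auc_se: float
    auc_ci_95: tuple[float, float]
    p_value_vs_chance: float
    youden_cutoff: float
    youden_j: float
    n_pos: int
    n_neg: int

    @property
    def cutoff_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "cutoff": self.thresholds,
            "sensitivity_pct": 100.0 * self.sensitivity,
            "specificity_pct": 100.0 * self.specificity,
            "youden_j": self.sensitivity + self.specificity - 1.0,
        })

    def curve_points(self) -> tuple[np.ndarray, np.ndarray]:
        """(FPR, TPR) pairs of the empirical curve, from (0,0) to (1,1)."""
        fpr = np.concatenate([[0.0], 1.0 - self.specificity[::-1], [1.0]])
        tpr = np.concatenate([[0.0], self.sensitivity[::-1], [1.0]])
        return fpr, tpr


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """DeLong structural components V10 (per positive) and V01 (per negative)."""
    cmp = (pos[:, None] > neg[None, :]).astype(float)
    cmp += 0.5 * (pos[:, None] == neg[None, :])
    return cmp.mean(axis=1), cmp.mean(axis=0), cmp.mean()


def roc_analysis(scores, labels) -> RocResult:
    """Empirical ROC of ``scores`` against binary ``labels`` (1 = responder).

    Thresholds are the distinct observed scores; the AUC is computed from
    midranks (exactly the trapezoidal area of the tie-grouped curve and the
    normalized Mann-Whitney U); the 95% CI uses DeLong's covariance method
    on the logit scale (falling back to a clipped Wald interval in the
    degenerate perfect-separation case).  Higher scores must indicate
    responders — the orientation is never flipped automatically.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have the same length")
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary (0/1)")
    pos, neg = scores[labels == 1], scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("degenerate labels: both classes must be present")
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 patients per class")

    n1, n0 = len(pos), len(neg)
    ranks = stats.rankdata(scores)  # midranks
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    v10, v01, _ = _delong_components(pos, neg)
    var = (np.var(v10, ddof=1) / n1 if n1 > 1 else 0.0) \
        + (np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0)
    se = math.sqrt(max(var, 0.0))
    z = stats.norm.ppf(0.975)
    if se > 0 and 0.0 < auc < 1.0:
        # logit-scale interval: respects the [0, 1] range and restores the
        # nominal coverage that a clipped Wald interval loses near 1
        logit = math.log(auc / (1.0 - auc))
        se_logit = se / (auc * (1.0 - auc))
        ci = (1.0 / (1.0 + math.exp(-(logit - z * se_logit))),
              1.0 / (1.0 + math.exp(-(logit + z * se_logit))))
    else:
        ci = (max(0.0, auc - z * se), min(1.0, auc + z * se))
    if se > 0:
        p_chance = 2.0 * stats.norm.sf(abs(auc - 0.5) / se)
    else:
        p_chance = 0.0 if auc != 0.5 else 1.0

    thresholds = np.unique(scores)
    sens = (pos[None, :] > thresholds[:, None]).mean(axis=1)
    spec = (neg[None, :] <= thresholds[:, None]).mean(axis=1)
    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first occurrence = lowest threshold on ties
    return RocResult(
        thresholds=thresholds, sensitivity=sens, specificity=spec,
        auc=float(auc), auc_se=se, auc_ci_95=ci,
        p_value_vs_chance=float(p_chance),
        youden_cutoff=float(thresholds[best]), youden_j=float(j[best]),
        n_pos=n1, n_neg=n0,
    )


def youden_optimal_cutoff(roc: RocResult) -> float:
    """Threshold maximizing sensitivity + specificity - 1.

    Ties are broken by the lowest threshold (favouring sensitivity); the
    classification rule is ``score > cutoff`` -> predicted responder.
    """
    j = roc.sensitivity + roc.specificity - 1.0
    return float(roc.thresholds[int(np.argmax(j))])


# --------------------------------------------------------------------------
# AUC-based sample size (Hanley-McNeil)
# --------------------------------------------------------------------------

@dataclass
class SampleSizeSpec:
    """Inputs and results of the AUC-based sample-size computation.

    ``allocation_ratio`` is negatives (nonresponders) per positive
    (responder).  ``variant='hanley-mcneil'`` (default) uses the asymptotic
    closed-form variance ``V(theta) = (Q1 - theta^2)/R + (Q2 - theta^2)``
    per positive subject; ``variant='exact'`` iterates the finite-sample
    Hanley-McNeil variance (which is slightly conservative and yields a
    larger n).
    """

    auc_null: float = 0.5
    auc_alt: float = 0.75
    alpha: float = 0.05  # two-sided
    power: float = 0.80
    allocation_ratio: float = 1.0
    dropout_rate: float = 0.10
    variant: str = "hanley-mcneil"
    # filled by sample_size_auc:
    n_positive: int | None = None
    n_negative: int | None = None
    n_total: int | None = None
    n_enrolled: int | None = None


def _q1(theta: float) -> float:
    return theta / (2.0 - theta)


def _q2(theta: float) -> float:
    return 2.0 * theta * theta / (1.0 + theta)


def _hm_variance(theta: float, n_pos: int, n_neg: int) -> float:
    """Finite-sample Hanley-McNeil variance of an empirical AUC."""
    return (theta * (1 - theta)
            + (n_pos - 1) * (_q1(theta) - theta ** 2)
            + (n_neg - 1) * (_q2(theta) - theta ** 2)) / (n_pos * n_neg)


def sample_size_auc(spec: SampleSizeSpec) -> SampleSizeSpec:
    """Patients needed to distinguish ``auc_alt`` from ``auc_null``.

    Default (closed-form Hanley-McNeil): smallest integer number of
    positives ``n+`` with

        n+ >= (z_{alpha/2} * sqrt(V(theta0)) + z_beta * sqrt(V(theta1)))^2
              / (theta1 - theta0)^2,
        V(theta) = (Q1 - theta^2)/R + (Q2 - theta^2),
        Q1 = theta/(2-theta),  Q2 = 2*theta^2/(1+theta),

    with ``R`` negatives per positive; ``n- = ceil(R * n+)``.  With the
    defaults (0.75 vs 0.5, two-sided alpha 0.05, power 0.80, R = 1) this
    gives 19 + 19 = 38 patients.  Enrollment inflates the total by the
    dropout rate, rounded to the nearest integer (38 -> 42 at 10%).
    """
    if not (0.5 <= spec.auc_null < spec.auc_alt < 1.0):
        raise ValueError(
            "unreachable power: need 0.5 <= auc_null < auc_alt < 1"
        )
    if not (0 < spec.alpha < 1 and 0 < spec.power < 1):
        raise ValueError("alpha and power must be in (0, 1)")
    if spec.allocation_ratio <= 0:
        raise ValueError("allocation_ratio must be positive")
    t0, t1, r = spec.auc_null, spec.auc_alt, spec.allocation_ratio
    za = stats.norm.ppf(1.0 - spec.alpha / 2.0)
    zb = stats.norm.ppf(spec.power)
    delta = t1 - t0

    if spec.variant == "hanley-mcneil":
        def v(theta):
            return (_q1(theta) - theta ** 2) / r + (_q2(theta) - theta ** 2)
        n_pos = math.ceil((za * math.sqrt(v(t0)) + zb * math.sqrt(v(t1))) ** 2
                          / delta ** 2)
    elif spec.variant == "exact":
        n_pos = None
        for n in range(2, 100000):
            n_neg = math.ceil(r * n)
            lhs = (za * math.sqrt(_hm_variance(t0, n, n_neg))
                   + zb * math.sqrt(_hm_variance(t1, n, n_neg)))
            if lhs <= delta:
                n_pos = n
                break
        if n_pos is None:  # pragma: no cover
            raise ValueError("unreachable power: no feasible sample size")
    else:
        raise ValueError(f"unknown variant {spec.variant!r}")

    n_neg = math.ceil(r * n_pos)
    n_total = n_pos + n_neg
    spec.n_positive = n_pos
    spec.n_negative = n_neg
    spec.n_total = n_total
    spec.n_enrolled = int(round(n_total * (1.0 + spec.dropout_rate)))
    return spec
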