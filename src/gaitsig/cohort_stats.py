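"""Group comparisons for demographic, clinical and spatiotemporal tables.

Implements the univariate toolkit used to compare an iNPH group against
healthy controls: descriptive summaries, a normality/variance gate that
recommends the appropriate two-sample test, pooled and Welch t-tests
(raw-data and summary-statistic entry points), the Mann-Whitney U test,
Fisher's exact test with odds ratio and Woolf confidence interval for
2x2 tables, and signed percent differences for reporting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "DescribeResult",
    "TTestResult",
    "TwoByTwoResult",
    "describe",
    "normality_and_variance_gate",
    "independent_t",
    "independent_t_from_stats",
    "mann_whitney_u",
    "fisher_or",
    "percent_difference",
]


@dataclass(frozen=True)
class DescribeResult:
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float
    range: float


@dataclass(frozen=True)
class TTestResult:
    """Two-sample t-test with Cohen's d.

    ``d`` always uses the pooled SD, even under the Welch variance
    policy, so a single effect-size convention applies across tests.
    """

    t: float
    df: float
    p: float
    d: float
    variance_policy: str

    def __post_init__(self):
        assert self.df > 0
        assert 0.0 <= self.p <= 1.0


@dataclass(frozen=True)
class TwoByTwoResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float
    cramers_v: float


def describe(values) -> DescribeResult:
    """Mean, sample SD (n-1), median, min, max and range of a numeric list."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("describe: empty input")
    sd = float(np.std(x, ddof=1)) if x.size >= 2 else float("nan")
    return DescribeResult(
        n=int(x.size),
        mean=float(np.mean(x)),
        sd=sd,
        median=float(np.median(x)),
        min=float(np.min(x)),
        max=float(np.max(x)),
        range=float(np.max(x) - np.min(x)),
    )


def normality_and_variance_gate(x, y, alpha: float = 0.05) -> str:
    """Recommend a two-sample test from Shapiro-Wilk and Levene screens.

    Shapiro-Wilk is run per group; Levene's test is centred at the median
    (Brown-Forsythe variant). Non-normal in either group -> "mann-whitney";
    normal with unequal variances -> "welch-t"; otherwise "pooled-t".
    Constant input makes normality undefined, so the non-parametric route
    is recommended with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("normality_and_variance_gate: need n >= 3 per group")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("constant sample: recommending mann-whitney")
        return "mann-whitney"
    p_x = stats.shapiro(x).pvalue
    p_y = stats.shapiro(y).pvalue
    if p_x < alpha or p_y < alpha:
        return "mann-whitney"
    p_lev = stats.levene(x, y, center="median").pvalue
    if p_lev < alpha:
        return "welch-t"
    return "pooled-t"


def _pooled_sd(m1, s1, n1, m2, s2, n2) -> float:
    return float(np.sqrt(((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)))


def independent_t_from_stats(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    variance_policy: str = "pooled",
) -> TTestResult:
    """Two-sample t-test from group summary statistics.

    Published tables print only (mean, SD, n), so this entry point lets
    printed summaries be re-tested directly; expect ~1% disagreement with
    statistics computed on raw data when the inputs are rounded to two
    decimals.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("independent_t: need n >= 2 per group")
    sp = _pooled_sd(mean1, sd1, n1, mean2, sd2, n2)
    if sp == 0:
        raise ValueError("independent_t: zero pooled variance")
    if variance_policy == "pooled":
        t, p = stats.ttest_ind_from_stats(
            mean1, sd1, n1, mean2, sd2, n2, equal_var=True
        )
        df = float(n1 + n2 - 2)
    elif variance_policy == "welch":
        t, p = stats.ttest_ind_from_stats(
            mean1, sd1, n1, mean2, sd2, n2, equal_var=False
        )
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    else:
        raise ValueError(f"unknown variance_policy {variance_policy!r}")
    d = (mean1 - mean2) / sp
    return TTestResult(
        t=float(t), df=float(df), p=float(p), d=float(d),
        variance_policy=variance_policy,
    )


def independent_t(x, y, variance_policy: str = "pooled") -> TTestResult:
    """Two-sample t-test on raw data (pooled or Welch variance policy)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return independent_t_from_stats(
        float(np.mean(x)), float(np.std(x, ddof=1)), x.size,
        float(np.mean(y)), float(np.std(y, ddof=1)), y.size,
        variance_policy=variance_policy,
    )


def mann_whitney_u(x, y, method: str = "asymptotic"):
    """Mann-Whitney U test, two-tailed.

    U counts pairs with x_i > y_j plus half-ties. ``method`` is
    "asymptotic" (normal approximation with tie correction and continuity
    correction, the large-sample default) or "exact" (full null
    distribution; no ties allowed by the exact method).

    Returns ``(U, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("mann_whitney_u: empty input")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def fisher_or(table, ci_z: float = stats.norm.ppf(0.975),
              two_sided_rule: str = "small-p") -> TwoByTwoResult:
    """Odds ratio, Woolf CI, Fisher exact p and Cramér's V for a 2x2 table.

    OR = ad/bc with the Woolf logit interval
    exp(ln OR ± z*sqrt(1/a + 1/b + 1/c + 1/d)). The exact two-sided p sums
    all tables at least as improbable as the observed one ("small-p" rule);
    ``two_sided_rule="doubling"`` instead doubles the smaller one-sided
    tail (capped at 1). V is from the uncorrected chi-square statistic.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.round(t)):
        raise ValueError("fisher_or: need a 2x2 table of nonnegative integers")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        raise ValueError("fisher_or: zero marginal total")
    a, b = t[0]
    c, d = t[1]
    if b * c == 0 or a * d == 0:
        raise ValueError("fisher_or: zero cell makes the odds ratio degenerate")
    odds = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = float(np.exp(np.log(odds) - ci_z * se))
    hi = float(np.exp(np.log(odds) + ci_z * se))
    if two_sided_rule == "small-p":
        _, p = stats.fisher_exact(t.astype(int), alternative="two-sided")
    elif two_sided_rule == "doubling":
        _, p_less = stats.fisher_exact(t.astype(int), alternative="less")
        _, p_greater = stats.fisher_exact(t.astype(int), alternative="greater")
        p = min(1.0, 2.0 * min(p_less, p_greater))
    else:
        raise ValueError(f"unknown two_sided_rule {two_sided_rule!r}")
    chi2 = stats.chi2_contingency(t, correction=False).statistic
    v = float(np.sqrt(chi2 / t.sum()))
    return TwoByTwoResult(
        odds_ratio=float(odds), ci_low=lo, ci_high=hi,
        p=float(p), cramers_v=v,
    )


def percent_difference(case_mean: float, control_mean: float) -> float:
    """Signed percent difference of the case mean relative to the control
    mean: 100*(case - control)/control. Round to integer for reporting."""
    if control_mean == 0:
        raise ValueError("percent_difference: zero reference mean")
    return 100.0 * (case_mean - control_mean) / control_mean
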