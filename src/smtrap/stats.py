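"""Statistical reporting layer.

Wraps the standard two-sample tests used throughout the analysis (Welch's
t, Mann-Whitney U, Spearman rank correlation), Bonferroni-adjusted
significance stars, box-and-whisker summaries (1.5×IQR whisker rule,
type-7 linear-interpolation quartiles), SEM, and single-exponential
lifetime fitting for photobleaching on-times.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass
class TestResult:
    statistic: float
    p_value: float
    test: str
    n1: int
    n2: int

    def stars(self, m: int = 1) -> str:
        return bonferroni_stars(self.p_value, m)


@dataclass
class CorrelationResult:
    rho: float
    p_value: float
    n: int


@dataclass
class BoxSummary:
    """Box-and-whisker summary: 1.5×IQR whiskers clamped to observed data."""

    min: float
    max: float
    median: float
    mean: float
    q1: float
    q3: float
    whisker_lo: float
    whisker_hi: float
    n: int


def welch_t(a, b) -> TestResult:
    """Two-sided Welch's t test (unequal variances, Welch–Satterthwaite dof)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    stat, p = sps.ttest_ind(a, b, equal_var=False)
    return TestResult(float(stat), float(p), "welch_t", len(a), len(b))


def mann_whitney(a, b) -> TestResult:
    """Two-sided Mann-Whitney U.

    Exact enumeration is used for small samples without ties (n ≤ 8 per
    group); otherwise the normal approximation with tie correction.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per group")
    ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    small = max(len(a), len(b)) <= 8
    method = "exact" if (small and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return TestResult(
        float(res.statistic), float(res.pvalue), "mann_whitney", len(a), len(b)
    )


def spearman(pairs) -> CorrelationResult:
    """Spearman's ρ on an (n, 2) array of paired observations."""
    arr = np.asarray(pairs, float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 3:
        raise ValueError("need an (n >= 3, 2) array of pairs")
    rho, p = sps.spearmanr(arr[:, 0], arr[:, 1])
    return CorrelationResult(float(rho), float(p), len(arr))


def bonferroni_stars(p: float, m: int = 1) -> str:
    """Significance stars at 0.05/0.01/0.001 divided by ``m`` comparisons.

    All comparisons are strict; with m = 3 the working thresholds are
    0.0167/0.0033/0.00033 (printed as 0.017/0.003/0.0003).
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if p < 0.001 / m:
        return "***"
    if p < 0.01 / m:
        return "**"
    if p < 0.05 / m:
        return "*"
    return ""


def sem(values) -> float:
    v = np.asarray(values, float)
    if len(v) < 2:
        raise ValueError("SEM needs at least 2 values")
    return float(np.std(v, ddof=1) / np.sqrt(len(v)))


def box_summary(values) -> BoxSummary:
    """Quartiles by linear interpolation; whiskers at the most extreme data
    points within 1.5×IQR of the box."""
    v = np.sort(np.asarray(values, float))
    if len(v) < 1:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    in_lo = v[v >= q1 - 1.5 * iqr]
    in_hi = v[v <= q3 + 1.5 * iqr]
    return BoxSummary(
        min=float(v.min()),
        max=float(v.max()),
        median=float(med),
        mean=float(v.mean()),
        q1=float(q1),
        q3=float(q3),
        whisker_lo=float(in_lo.min()),
        whisker_hi=float(in_hi.max()),
        n=len(v),
    )


def fit_exponential_lifetime(
    durations, truncation: float | None = None
) -> float:
    """ML mean lifetime of a single-exponential decay.

    For untruncated data the MLE of the mean is the sample mean.  When
    events shorter than a threshold ``truncation`` are unobservable (e.g.
    detected dwells must exceed the residency threshold), memorylessness
    gives E[X | X > T] = T + τ, so the estimator is mean − T.
    """
    d = np.asarray(durations, float)
    if len(d) < 10:
        raise ValueError("need at least 10 durations")
    if np.any(d <= 0):
        raise ValueError("durations must be positive")
    if truncation is None:
        return float(np.mean(d))
    if np.any(d < truncation):
        raise ValueError("durations below the stated truncation threshold")
    return float(np.mean(d) - truncation)
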