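"""Outlier screening and two-sample t-tests.

The statistical layer mirrors a common workflow in small-n imaging studies:
each experimental group is first screened for outliers with the modified
Thompson Tau procedure, then the cleaned groups are compared with a
two-tailed Student's t-test. A summary-statistics t-test (from n, mean, SEM)
is provided for checking published values when raw data are unavailable.

Modified Thompson Tau
---------------------
For a sample of size n with mean x̄ and sample SD s, the rejection threshold
is ``tau * s`` with::

    tau = t_{alpha/2, n-2} * (n - 1) / (sqrt(n) * sqrt(n - 2 + t_{alpha/2, n-2}^2))

The single most deviant point is removed if |x - x̄| exceeds the threshold,
and the procedure repeats on the reduced sample until nothing exceeds it or
only two points remain. At most one point is removed per iteration; among
tied deviations the larger value is removed first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import SampleSizeError

__all__ = [
    "OutlierScreenResult",
    "TTestResult",
    "thompson_tau_screen",
    "t_test_two_tailed",
    "t_test_from_summary",
]


@dataclass
class OutlierScreenResult:
    """Outcome of an iterative Thompson-Tau screen.

    ``removed`` is in removal order; ``tau_thresholds`` holds the ``tau * s``
    cutoff evaluated at each iteration (including the final one that removed
    nothing).
    """

    retained: np.ndarray
    removed: np.ndarray
    tau_thresholds: np.ndarray
    alpha: float


@dataclass
class TTestResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    variant: str
    group_summaries: tuple  # ((n, mean, sem), (n, mean, sem))


def tau_critical(n: int, alpha: float) -> float:
    """Modified Thompson Tau multiplier for a sample of size n."""
    t = sps.t.ppf(1 - alpha / 2, n - 2)
    return t * (n - 1) / (math.sqrt(n) * math.sqrt(n - 2 + t * t))


def thompson_tau_screen(values, alpha: float = 0.05) -> OutlierScreenResult:
    """Iteratively remove outliers by the modified Thompson Tau rule.

    Requires n >= 3 and ``alpha`` in (0, 0.5). A zero-SD sample terminates
    immediately with no removals.
    """
    data = np.asarray(values, dtype=float).ravel()
    if data.size < 3:
        raise SampleSizeError(f"Thompson Tau screen needs n >= 3, got {data.size}")
    if not (0 < alpha < 0.5):
        raise SampleSizeError(f"alpha must be in (0, 0.5), got {alpha}")

    current = data.copy()
    removed: list[float] = []
    thresholds: list[float] = []
    while current.size >= 3:
        s = current.std(ddof=1)
        if s == 0:
            break
        mean = current.mean()
        cutoff = tau_critical(current.size, alpha) * s
        thresholds.append(cutoff)
        deviations = np.abs(current - mean)
        if deviations.max() <= cutoff:
            break
        worst = np.flatnonzero(deviations == deviations.max())
        # tie: remove the larger value first
        idx = worst[np.argmax(current[worst])]
        removed.append(float(current[idx]))
        current = np.delete(current, idx)
    return OutlierScreenResult(
        retained=current,
        removed=np.asarray(removed),
        tau_thresholds=np.asarray(thresholds),
        alpha=alpha,
    )


def _summaries(a: np.ndarray, b: np.ndarray) -> tuple:
    return tuple(
        (g.size, float(g.mean()), float(g.std(ddof=1) / math.sqrt(g.size)))
        for g in (a, b)
    )


def _degenerate(mean1: float, mean2: float, df: float, variant: str, summaries):
    """Convention when both groups have zero spread: p=1 if means equal."""
    if mean1 == mean2:
        return TTestResult(0.0, df, 1.0, variant, summaries)
    sign = 1.0 if mean1 > mean2 else -1.0
    return TTestResult(sign * math.inf, df, 0.0, variant, summaries)


def t_test_two_tailed(group_a, group_b, variant: str = "pooled") -> TTestResult:
    """Two-sample two-tailed t-test on raw data.

    ``variant="pooled"`` is the classical Student's test (equal variances);
    ``variant="welch"`` uses the Welch-Satterthwaite approximation.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    a = np.asarray(group_a, dtype=float).ravel()
    b = np.asarray(group_b, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise SampleSizeError("each group needs n >= 2")
    summaries = _summaries(a, b)
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        return _degenerate(a.mean(), b.mean(), float(a.size + b.size - 2),
                           variant, summaries)
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    return TTestResult(
        t_statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        variant=variant,
        group_summaries=summaries,
    )


def t_test_from_summary(
    n1: int,
    mean1: float,
    sem1: float,
    n2: int,
    mean2: float,
    sem2: float,
    variant: str = "welch",
) -> TTestResult:
    """Two-tailed t-test from per-group (n, mean, SEM) summary statistics.

    The Welch variant uses ``t = (mean1 - mean2) / sqrt(sem1^2 + sem2^2)``
    with Welch-Satterthwaite degrees of freedom; the pooled variant
    reconstructs the SDs (``sd = sem * sqrt(n)``) and applies the classical
    pooled-variance test.
    """
    if variant not in ("pooled", "welch"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    if n1 < 2 or n2 < 2:
        raise SampleSizeError("each group needs n >= 2")
    if sem1 < 0 or sem2 < 0:
        raise ValueError("SEMs must be >= 0")
    summaries = ((n1, mean1, sem1), (n2, mean2, sem2))
    if sem1 == 0 and sem2 == 0:
        df = float(n1 + n2 - 2)
        return _degenerate(mean1, mean2, df, variant, summaries)
    if variant == "welch":
        se_sq = sem1**2 + sem2**2
        t = (mean1 - mean2) / math.sqrt(se_sq)
        df = se_sq**2 / (sem1**4 / (n1 - 1) + sem2**4 / (n2 - 1))
        p = 2 * sps.t.sf(abs(t), df)
    else:
        res = sps.ttest_ind_from_stats(
            mean1, sem1 * math.sqrt(n1), n1, mean2, sem2 * math.sqrt(n2), n2,
            equal_var=True,
        )
        t, p = float(res.statistic), float(res.pvalue)
        df = float(n1 + n2 - 2)
    return TTestResult(
        t_statistic=float(t),
        degrees_of_freedom=float(df),
        p_value=float(p),
        variant=variant,
        group_summaries=summaries,
    )
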