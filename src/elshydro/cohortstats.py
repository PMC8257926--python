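"""Univariate and bivariate cohort statistics.

Thin, convention-fixing wrappers over scipy.stats: Fisher's exact test for
2x2 tables (two-sided by the probability-mass rule, matching R's default),
the Mann-Whitney U test (midranks, tie-corrected normal approximation with
continuity correction; exact enumeration when both samples have n <= 8), and
the ordinary-least-squares regression of the ELS ratio on the logarithmic
days since symptom onset, x = log10(1 + interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "RegressionLine",
    "fisher_exact_2x2",
    "mann_whitney_u",
    "onset_regression",
    "format_p",
]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    estimate: float
    method: str


@dataclass(frozen=True)
class RegressionLine:
    """OLS line y = intercept + slope * x with the zero-slope t-test p."""

    intercept: float
    slope: float
    p_slope: float
    n: int

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)


def fisher_exact_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher's exact test on the table [[a, b], [c, d]].

    The two-sided p sums hypergeometric probabilities (margins fixed) of all
    tables no more probable than the observed one; the estimate is the
    sample odds ratio ad/bc (inf when bc = 0).
    """
    for v in (a, b, c, d):
        if not (isinstance(v, (int, np.integer)) and v >= 0):
            raise ValueError("counts must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("table total must be positive")
    odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return TestResult(
        statistic=float(odds), p_value=float(p), estimate=float(odds),
        method="Fisher's exact test",
    )


def mann_whitney_u(x, y) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Midrank U statistic; p by tie-corrected normal approximation with
    continuity correction, switching to exact enumeration when both samples
    have at most 8 observations (and no ties).  The estimate is U1 for the
    first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    has_ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 8 and y.size <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return TestResult(
        statistic=float(res.statistic), p_value=float(res.pvalue),
        estimate=float(res.statistic), method=f"Mann-Whitney U ({method})",
    )


def onset_regression(intervals_days, ratios_pct) -> RegressionLine:
    """Regress the ELS ratio (percent) on x = log10(1 + days since onset)."""
    t = np.asarray(intervals_days, dtype=float)
    y = np.asarray(ratios_pct, dtype=float)
    if t.shape != y.shape or t.size < 3:
        raise ValueError("need >= 3 paired observations")
    if (t < 0).any():
        raise ValueError("intervals must be non-negative")
    x = np.log10(1.0 + t)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in log-interval; slope undefined")
    fit = stats.linregress(x, y)
    return RegressionLine(
        intercept=float(fit.intercept), slope=float(fit.slope),
        p_slope=float(fit.pvalue), n=t.size,
    )


def format_p(p: float) -> str:
    """Report-style p formatting: two decimals when p >= 0.01, else '<0.001'
    style."""
    if np.isnan(p):
        return "NA"
    if p < 0.001:
        return "<0.001"
    if p < 0.01:
        return f"{p:.3f}"
    return f"{p:.2f}"
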