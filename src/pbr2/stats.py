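"""Method-comparison statistics: regression, Bland-Altman, ICC.

Used to compare R2 estimates from the phase-based pipeline against a
reference method, and to quantify test-retest repeatability of repeated
acquisitions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

__all__ = [
    "PairedMeasurements",
    "RegressionResult",
    "BlandAltmanResult",
    "linear_regression",
    "bland_altman",
    "icc",
]


@dataclass(frozen=True)
class PairedMeasurements:
    """Paired reference (x) and test (y) values, e.g. R2 in s^-1."""

    x: np.ndarray
    y: np.ndarray
    labels: tuple | None = None

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("x and y must be matching 1-D arrays")
        if x.size < 3:
            raise ValueError("need at least 3 pairs")
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("values must be finite")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    slope_ci: tuple
    intercept_ci: tuple


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    loa_low: float
    loa_high: float


def linear_regression(data: PairedMeasurements) -> RegressionResult:
    """Ordinary least squares y ~ x with t-based 95% confidence intervals."""
    if np.ptp(data.x) == 0:
        raise ValueError("degenerate design: x is constant")
    X = sm.add_constant(data.x)
    fit = sm.OLS(data.y, X).fit()
    ci = fit.conf_int(alpha=0.05)
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        slope_ci=(float(ci[1][0]), float(ci[1][1])),
        intercept_ci=(float(ci[0][0]), float(ci[0][1])),
    )


def bland_altman(data: PairedMeasurements) -> BlandAltmanResult:
    """Mean difference (bias) and 95% limits of agreement bias±1.96 SD."""
    d = data.y - data.x
    bias = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    return BlandAltmanResult(bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)


def icc(rep1, rep2) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Computed from the two-way ANOVA decomposition of an n-subject x 2-repeat
    table.  Degenerate tables with no between-subject and no residual
    variance return 0.0 (the defined limit) rather than raising.
    """
    y = np.column_stack(
        [np.asarray(rep1, dtype=float), np.asarray(rep2, dtype=float)]
    )
    n, k = y.shape
    if n < 3:
        raise ValueError("need at least 3 subjects")
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((y - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0 or not np.isfinite(denom):
        return 0.0
    return float((msr - mse) / denom)
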