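"""Inferential statistics used throughout the analysis.

Chi-square tests are uncorrected Pearson statistics (no Yates continuity
correction): the goodness-of-fit variant against uniform expectation, and
the 2×2 contingency variant. Regression is a two-predictor OLS of the
compound estimate on the larger and smaller constituent estimates, reported
as standardized coefficients and partial correlations — the form in which
configural-weighted-average and potential-surprise predictions about which
constituent dominates are tested. Percentages are rounded half-away-from-
zero to one decimal, matching the convention of published reports.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "ChiSqResult", "FitResult", "chisq_gof", "chisq_2x2",
    "ols_two", "paired_t", "proportion_pct",
]


@dataclass(frozen=True)
class ChiSqResult:
    statistic: float
    df: int
    p: float


@dataclass(frozen=True)
class FitResult:
    """Two-predictor OLS summary.

    ``beta_large``/``beta_small`` are standardized coefficients;
    ``partial_large``/``partial_small`` are partial correlations of the
    response with each predictor controlling for the other. ``collinear``
    flags (near-)collinear predictors, for which partials are NaN.
    """

    r_squared: float
    intercept: float
    beta_large: float
    beta_small: float
    partial_large: float
    partial_small: float
    p_large: float
    p_small: float
    n: int
    collinear: bool = False


def chisq_gof(observed: list[int] | np.ndarray) -> ChiSqResult:
    """Pearson goodness-of-fit against a uniform expectation.

    statistic = Σ (O−E)²/E with E = total/k, df = k−1.
    """
    obs = np.asarray(observed, dtype=float)
    if obs.size < 2:
        raise ValueError("need at least 2 cells")
    if np.any(obs < 0):
        raise ValueError("negative counts")
    if obs.sum() <= 0:
        raise ValueError("zero total")
    res = sps.chisquare(obs)
    return ChiSqResult(float(res.statistic), int(obs.size - 1), float(res.pvalue))


def chisq_2x2(a: int, b: int, c: int, d: int) -> ChiSqResult:
    """Uncorrected Pearson chi-square on a 2×2 table [[a, b], [c, d]], df = 1."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero margin")
    res = sps.chi2_contingency(table, correction=False)
    return ChiSqResult(float(res.statistic), 1, float(res.pvalue))


def ols_two(y, x_large, x_small) -> FitResult:
    """OLS fit y = c + b_L·x_large + b_S·x_small with standardized output.

    Standardized coefficients rescale the raw slopes by sd(x)/sd(y); when
    the response is constant both are 0 and R² is 0. Partial correlations
    come from residualizing y and each predictor on the other. Coefficient
    p-values are two-sided t tests from the raw fit.
    """
    y = np.asarray(y, dtype=float)
    xl = np.asarray(x_large, dtype=float)
    xs = np.asarray(x_small, dtype=float)
    n = y.size
    if not (xl.size == xs.size == n):
        raise ValueError("input vectors must share one length")
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(xl) == 0 or np.ptp(xs) == 0:
        raise ValueError("constant predictor")

    X = sm.add_constant(np.column_stack([xl, xs]))
    collinear = np.linalg.matrix_rank(X) < 3
    fit = sm.OLS(y, X).fit()
    sd_y = y.std(ddof=1)
    if sd_y == 0:
        return FitResult(0.0, float(y[0]), 0.0, 0.0, np.nan, np.nan,
                         np.nan, np.nan, n, collinear)
    beta_l = float(fit.params[1] * xl.std(ddof=1) / sd_y)
    beta_s = float(fit.params[2] * xs.std(ddof=1) / sd_y)

    if collinear:
        pl = ps = np.nan
    else:
        pl = _partial_corr(y, xl, xs)
        ps = _partial_corr(y, xs, xl)
    return FitResult(
        r_squared=float(fit.rsquared),
        intercept=float(fit.params[0]),
        beta_large=beta_l,
        beta_small=beta_s,
        partial_large=pl,
        partial_small=ps,
        p_large=float(fit.pvalues[1]),
        p_small=float(fit.pvalues[2]),
        n=int(n),
        collinear=bool(collinear),
    )


def _partial_corr(y: np.ndarray, x: np.ndarray, z: np.ndarray) -> float:
    """corr(y, x | z) by residualizing both on z (with intercept)."""
    Z = sm.add_constant(z)
    ry = y - Z @ np.linalg.lstsq(Z, y, rcond=None)[0]
    rx = x - Z @ np.linalg.lstsq(Z, x, rcond=None)[0]
    denom = np.sqrt((ry ** 2).sum() * (rx ** 2).sum())
    if denom == 0:
        return float("nan")
    return float((ry * rx).sum() / denom)


def paired_t(a, b) -> tuple[float, int]:
    """Paired t statistic and df: t = mean(d) / (sd(d)/√n), df = n−1, d = a−b."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size != b.size:
        raise ValueError("vectors must share one length")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    if d.std(ddof=1) == 0:
        if d.mean() == 0:
            return 0.0, int(a.size - 1)
        raise ValueError("zero-variance differences")
    res = sps.ttest_rel(a, b)
    return float(res.statistic), int(a.size - 1)


def proportion_pct(k: int, n: int) -> float:
    """100·k/n rounded half-away-from-zero to one decimal."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 <= k <= n):
        raise ValueError("k must satisfy 0 <= k <= n")
    pct = Decimal(100 * k) / Decimal(n)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
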