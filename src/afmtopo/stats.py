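"""Statistical layer: height-spectrum regression, ratios, fold-changes and
rank-sum comparisons.

The central observation the statistics support is that the peak roughness
intensity S_max (nm^2) tracks the cell height h_max (nm) as cells spread and
flatten during activation. Per activator arm and spectral order this is
summarised by the Pearson coefficient r and the ordinary-least-squares slope
b of S_max on h_max (units nm^2/nm = nm); slopes of the two activator arms
are compared as a plain ratio, and spectral decline over time as a
control/activated fold-change.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats as sps

__all__ = [
    "RegressionResult", "ComparisonResult",
    "correlate_height_spectrum", "coefficient_ratio", "fold_change",
    "mann_whitney", "slope_confidence_interval",
]

#: significance stars
_STARS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass
class RegressionResult:
    """Pearson r and OLS regression of S_max (nm^2) on h_max (nm)."""

    r: float
    b_nm: float
    intercept_nm2: float
    b_stderr_nm: float
    n: int
    order: str = ""
    activator: str = ""

    def __post_init__(self):
        if not -1.0 <= self.r <= 1.0 + 1e-12:
            raise ValueError("Pearson r outside [-1, 1]")
        if self.n < 3:
            raise ValueError("need n >= 3")


@dataclass
class ComparisonResult:
    """Two-sided rank-sum comparison."""

    statistic: float
    p_value: float
    stars: str

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _stars(p: float) -> str:
    for cut, mark in _STARS:
        if p < cut:
            return mark
    return "ns"


def correlate_height_spectrum(pairs, order: str = "",
                              activator: str = "") -> RegressionResult:
    """Pearson r and least-squares slope of S_max on h_max.

    ``pairs`` is a sequence of (h_max_nm, S_max_nm2) tuples pooled over time
    points within one activator arm and spectral order.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (h_max, S_max) pairs")
    h, s = arr[:, 0], arr[:, 1]
    if np.ptp(h) == 0:
        raise ValueError("degenerate input: h_max has zero variance")
    fit = sps.linregress(h, s)
    return RegressionResult(r=float(fit.rvalue), b_nm=float(fit.slope),
                            intercept_nm2=float(fit.intercept),
                            b_stderr_nm=float(fit.stderr), n=len(h),
                            order=order, activator=activator)


def slope_confidence_interval(result: RegressionResult,
                              level: float = 0.95) -> tuple[float, float]:
    """Two-sided t confidence interval for the regression slope."""
    t = sps.t.ppf(0.5 + level / 2.0, result.n - 2)
    return (result.b_nm - t * result.b_stderr_nm,
            result.b_nm + t * result.b_stderr_nm)


def coefficient_ratio(b_num_nm: float, b_den_nm: float,
                      decimals: int = 2) -> float:
    """Ratio of two regression slopes, rounded at ``decimals``.

    Computed in exact rational arithmetic with a single terminal rounding
    step, so e.g. 0.86/1.12 prints as 0.77 with no float drift.
    """
    if b_den_nm == 0:
        raise ZeroDivisionError("denominator slope is zero")
    q = Fraction(str(float(b_num_nm))) / Fraction(str(float(b_den_nm)))
    return float(round(q, decimals))


def fold_change(value_control: float, value_t: float) -> float:
    """Control-over-activated fold-change, to 2 significant figures."""
    if value_control <= 0 or value_t <= 0:
        raise ValueError("fold change requires positive values")
    q = Fraction(str(float(value_control))) / Fraction(str(float(value_t)))
    if q == 0:
        return 0.0
    exponent = int(np.floor(np.log10(float(q))))
    scale = Fraction(10) ** (exponent - 1)
    return float(round(q / scale) * scale)


def mann_whitney(sample_a, sample_b) -> ComparisonResult:
    """Two-sided Mann-Whitney U comparison with significance stars.

    The exact null distribution is used when the smaller sample has at most
    8 observations and there are no ties; otherwise the normal approximation
    with tie correction. Stars: * p<0.05, ** p<0.01, *** p<0.001.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each sample needs at least 3 observations")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(a), len(b)) <= 8 and not has_ties) \
        else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return ComparisonResult(statistic=float(res.statistic),
                            p_value=float(res.pvalue),
                            stars=_stars(float(res.pvalue)))
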