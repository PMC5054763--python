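"""Method-comparison statistics for paired measurement series.

Everything needed to judge agreement between two instruments measuring the
same head postures: Pearson correlation with an exact t-based p-value,
ordinary least-squares calibration line, Bland–Altman bias and 95% limits
of agreement, restriction of pairs to an instrument's operational range,
and intraclass correlation coefficients from the two-way random-effects
ANOVA decomposition (absolute agreement by default, consistency behind a
flag).

The statsmodels-style surface is :class:`MethodComparison` (built from two
series or a tidy paired table) whose ``fit()`` returns
:class:`AgreementResults` with a ``summary()`` table and a Bland–Altman
plot method.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import UndefinedStatisticError

__all__ = [
    "AgreementResults",
    "IccResult",
    "MethodComparison",
    "pearson",
    "linear_regression",
    "bland_altman",
    "BlandAltman",
    "restrict_to_operational_range",
    "DEFAULT_OPERATIONAL_BOUNDS",
    "icc",
]

#: Default per-axis symmetric operational bounds (degrees) used when
#: restricting agreement analysis to the tracker's accurate range.
DEFAULT_OPERATIONAL_BOUNDS = {"yaw": 30.0, "pitch": 20.0, "roll": 50.0}


def _as_arrays(x, y, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D series")
    if len(x) < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {len(x)}")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("series must be finite")
    return x, y


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Sample Pearson correlation and two-sided p-value.

    The p-value comes from the exact t transform t = r·sqrt((n−2)/(1−r²))
    with n − 2 degrees of freedom.

    Raises
    ------
    UndefinedStatisticError
        If either series has zero variance.
    """
    x, y = _as_arrays(x, y, 3)
    if np.std(x) == 0 or np.std(y) == 0:
        raise UndefinedStatisticError(
            "correlation undefined for a zero-variance series")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def linear_regression(x: Sequence[float], y: Sequence[float]
                      ) -> tuple[float, float, float]:
    """Ordinary least squares of y on x: (gradient, intercept, R²).

    R² equals the squared Pearson correlation (identity for simple OLS
    with intercept).

    Raises
    ------
    UndefinedStatisticError
        If x is constant (singular design).
    """
    x, y = _as_arrays(x, y, 3)
    if np.std(x) == 0:
        raise UndefinedStatisticError("regression undefined for constant x")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue ** 2)


@dataclass(frozen=True)
class BlandAltman:
    """Bland–Altman agreement: bias and limits in the units of the input
    (degrees here), plus the per-pair (mean, difference) points."""

    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    means: np.ndarray
    diffs: np.ndarray
    multiplier: float = 1.96

    @property
    def n_pairs(self) -> int:
        return len(self.diffs)


def bland_altman(x: Sequence[float], y: Sequence[float],
                 loa_multiplier: float = 1.96) -> BlandAltman:
    """Bland–Altman analysis of two paired series.

    Differences are d = y − x (tracker minus comparator); bias = mean(d);
    limits of agreement = bias ± multiplier · SD(d) with the sample
    (n − 1) standard deviation. The classical reference axis, mean(x, y)
    per pair, is returned for plotting.
    """
    x, y = _as_arrays(x, y, 2)
    d = y - x
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return BlandAltman(bias=bias,
                       loa_low=bias - loa_multiplier * sd,
                       loa_high=bias + loa_multiplier * sd,
                       sd_diff=sd,
                       means=(x + y) / 2.0, diffs=d,
                       multiplier=loa_multiplier)


def restrict_to_operational_range(pairs: pd.DataFrame, axis: str,
                                  range_bounds_deg: dict | float | None = None,
                                  reference_col: str = "instrument_a_deg",
                                  ) -> tuple[pd.DataFrame, int, int]:
    """Keep pairs whose comparator reading lies within ±bound for the axis.

    ``range_bounds_deg`` may be a per-axis dict (default: the tracker's
    documented ±30° yaw / ±20° pitch / ±50° roll) or a single number.
    Returns (kept pairs, n_kept, n_discarded).
    """
    if range_bounds_deg is None:
        range_bounds_deg = DEFAULT_OPERATIONAL_BOUNDS
    bound = (float(range_bounds_deg[axis]) if isinstance(range_bounds_deg, dict)
             else float(range_bounds_deg))
    if bound < 0:
        raise ValueError("bound must be non-negative")
    sub = pairs[pairs["axis"] == axis] if "axis" in pairs.columns else pairs
    keep = sub[np.abs(sub[reference_col]) <= bound]
    return keep, len(keep), len(sub) - len(keep)


@dataclass(frozen=True)
class IccResult:
    """Intraclass correlation from a complete (poses × repeats) matrix."""

    icc_single_measures: float
    icc_average_measures: float
    n_poses: int
    n_repeats: int
    model: str = "absolute_agreement"


def icc(matrix: np.ndarray, mode: str = "average",
        model: str = "absolute_agreement") -> IccResult:
    """Two-way random-effects intraclass correlation coefficient.

    Rows are the measured targets (poses), columns the repeated
    measurements (subjects / occasions). From the two-way ANOVA mean
    squares MSR (rows), MSC (columns) and MSE (residual):

    * absolute agreement, single:  ICC(2,1) = (MSR − MSE) /
      (MSR + (k−1)·MSE + k·(MSC − MSE)/n)
    * absolute agreement, average: ICC(2,k) = (MSR − MSE) /
      (MSR + (MSC − MSE)/n)
    * consistency, single:  ICC(3,1) = (MSR − MSE) / (MSR + (k−1)·MSE)
    * consistency, average: ICC(3,k) = (MSR − MSE) / MSR

    ``mode`` ("average" or "single") only selects the headline value when
    printing; both are always stored.

    Raises
    ------
    UndefinedStatisticError
        On an incomplete matrix (NaNs), fewer than 2 rows/columns, or zero
        total variance.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise UndefinedStatisticError("need a (>=2 poses) x (>=2 repeats) matrix")
    if not np.all(np.isfinite(M)):
        raise UndefinedStatisticError("matrix has missing cells")
    if mode not in ("average", "single"):
        raise ValueError("mode must be 'average' or 'single'")
    if model not in ("absolute_agreement", "consistency"):
        raise ValueError("model must be 'absolute_agreement' or 'consistency'")
    n, k = M.shape
    grand = M.mean()
    if np.allclose(M, grand):
        raise UndefinedStatisticError("zero total variance")
    row_means = M.mean(axis=1)
    col_means = M.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((M - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if model == "absolute_agreement":
        single = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        average = (msr - mse) / (msr + (msc - mse) / n)
    else:
        single = (msr - mse) / (msr + (k - 1) * mse)
        average = (msr - mse) / msr
    return IccResult(icc_single_measures=float(single),
                     icc_average_measures=float(average),
                     n_poses=n, n_repeats=k, model=model)


@dataclass(frozen=True)
class AgreementResults:
    """Full agreement analysis between two instruments on one axis."""

    axis: str
    pearson_r: float
    p_value: float
    gradient: float
    intercept_deg: float
    r_squared: float
    bland: BlandAltman
    n_pairs: int
    n_discarded: int = 0

    def summary(self) -> str:
        p = ("< 0.0001" if self.p_value < 1e-4 else f"= {self.p_value:.4g}")
        lines = [
            f"Method comparison ({self.axis}), n = {self.n_pairs}"
            + (f" ({self.n_discarded} outside range)" if self.n_discarded else ""),
            "=" * 52,
            f"Pearson r            {self.pearson_r:8.3f}   (P {p})",
            f"OLS gradient         {self.gradient:8.3f}",
            f"OLS intercept        {self.intercept_deg:8.2f} deg",
            f"R squared            {self.r_squared:8.3f}",
            f"Bland-Altman bias    {self.bland.bias:8.2f} deg",
            f"Limits of agreement  {self.bland.loa_low:8.2f} to "
            f"{self.bland.loa_high:.2f} deg",
        ]
        return "\n".join(lines)

    def plot_bland_altman(self, ax=None):
        """Scatter of per-pair differences against means with bias and
        limits-of-agreement lines. Returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        b = self.bland
        ax.scatter(b.means, b.diffs, s=14, alpha=0.7)
        ax.axhline(b.bias, color="k", lw=1)
        for y in (b.loa_low, b.loa_high):
            ax.axhline(y, color="k", lw=1, ls="--")
        ax.set_xlabel(f"mean of instruments ({self.axis}, deg)")
        ax.set_ylabel("difference (deg)")
        ax.set_title(f"Bland-Altman: {self.axis}")
        return ax


class MethodComparison:
    """Agreement model between a comparator and a tracker series.

    Parameters
    ----------
    x, y
        Paired readings: x the comparator (reference instrument), y the
        instrument under test.
    axis
        Label for reporting ("yaw", "pitch", "roll" or anything else).

    ``fit()`` computes correlation, the calibration regression of y on x,
    and the Bland–Altman analysis in one pass.
    """

    def __init__(self, x: Sequence[float], y: Sequence[float],
                 axis: str = "measurement"):
        self.x, self.y = _as_arrays(x, y, 2)
        self.axis = axis
        self.n_discarded = 0

    @classmethod
    def from_dataframe(cls, pairs: pd.DataFrame, axis: str,
                       restrict_range: dict | float | None = None,
                       comparator_col: str = "instrument_a_deg",
                       tracker_col: str = "instrument_b_deg",
                       ) -> "MethodComparison":
        """Build from a tidy paired table (columns subject, axis,
        target_deg, instrument_a_deg, instrument_b_deg), optionally
        restricted to the comparator's operational range."""
        sub = pairs[pairs["axis"] == axis]
        discarded = 0
        if restrict_range is not None:
            sub, _, discarded = restrict_to_operational_range(
                sub, axis, restrict_range, reference_col=comparator_col)
        obj = cls(sub[comparator_col].to_numpy(),
                  sub[tracker_col].to_numpy(), axis=axis)
        obj.n_discarded = discarded
        return obj

    def fit(self, loa_multiplier: float = 1.96) -> AgreementResults:
        r, p = pearson(self.x, self.y)
        gradient, intercept, r2 = linear_regression(self.x, self.y)
        ba = bland_altman(self.x, self.y, loa_multiplier)
        return AgreementResults(axis=self.axis, pearson_r=r, p_value=p,
                                gradient=gradient, intercept_deg=intercept,
                                r_squared=r2, bland=ba, n_pairs=len(self.x),
                                n_discarded=self.n_discarded)
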