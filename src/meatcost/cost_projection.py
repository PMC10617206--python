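"""Linear trend fitting and projection of annual healthcare cost series.

Annual direct healthcare costs (BRL, one observation per year) are fitted
with ordinary least squares on calendar year — centered before fitting so
the intercept is the cost at the mean observation year — and projected to
target years with a 95% confidence interval for the mean response
(t-distribution on n-2 degrees of freedom).  Projected local-currency
amounts are converted to international (PPP) dollars by dividing by the
purchasing-power-parity factor: 2.226 for current (2018) costs, 2.281 for
projected costs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import (
    DegenerateDesignError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "PPP_CURRENT",
    "PPP_FUTURE",
    "CostTrend",
    "CostProjection",
    "fit_trend",
    "project",
    "ppp_convert",
    "load_cost_series",
]

#: PPP conversion factor (BRL per international dollar) for current costs.
PPP_CURRENT = 2.226
#: PPP conversion factor for projected (future) costs.
PPP_FUTURE = 2.281


@dataclass(frozen=True)
class CostProjection:
    """Projected cost at one target year with a 95% mean-response CI."""

    year: int
    cost: float
    ci: tuple[float, float]

    def __post_init__(self) -> None:
        lo, hi = self.ci
        if not (lo <= self.cost <= hi):
            raise InvalidParameterError(
                f"projection {self.cost} outside its interval ({lo}, {hi})"
            )


@dataclass(frozen=True)
class CostTrend:
    """Fitted linear cost trend.

    ``intercept`` is the fitted mean cost at ``year_mean`` (the centered
    origin); ``slope`` is cost units per calendar year; ``sigma2`` the
    residual variance on n-2 degrees of freedom; ``sxx`` the centered
    sum of squares of the year regressor.
    """

    intercept: float
    slope: float
    sigma2: float
    n: int
    year_mean: float
    sxx: float

    @property
    def df_resid(self) -> int:
        return self.n - 2

    def predict(self, year) -> np.ndarray | float:
        y = np.asarray(year, dtype=float)
        out = self.intercept + self.slope * (y - self.year_mean)
        return float(out) if out.ndim == 0 else out


def fit_trend(series: pd.DataFrame | None = None, *, year=None, cost=None) -> CostTrend:
    """OLS fit of annual cost on (centered) calendar year.

    Accepts either a frame with ``year`` and a cost column (``cost_brl``
    or ``cost``) or explicit ``year=``/``cost=`` arrays.

    Raises
    ------
    InsufficientDataError
        Fewer than 3 observations.
    DegenerateDesignError
        All observations share one year.
    """
    if series is not None:
        year = series["year"].to_numpy(dtype=float)
        col = "cost_brl" if "cost_brl" in series.columns else "cost"
        cost = series[col].to_numpy(dtype=float)
    year = np.asarray(year, dtype=float)
    cost = np.asarray(cost, dtype=float)
    if year.size != cost.size:
        raise InvalidParameterError("year and cost must have equal length")
    if year.size < 3:
        raise InsufficientDataError(
            f"need at least 3 annual observations, got {year.size}"
        )
    if np.any(cost < 0):
        raise InvalidParameterError("costs must be non-negative")
    year_mean = float(year.mean())
    x = year - year_mean
    sxx = float(np.sum(x**2))
    if sxx == 0.0:
        raise DegenerateDesignError("all observations share a single year")
    res = sm.OLS(cost, sm.add_constant(x)).fit()
    return CostTrend(
        intercept=float(res.params[0]),
        slope=float(res.params[1]),
        sigma2=float(res.mse_resid),
        n=int(year.size),
        year_mean=year_mean,
        sxx=sxx,
    )


def project(model: CostTrend, target_year: int, level: float = 0.95) -> CostProjection:
    """Point projection with a symmetric 95% CI for the mean response.

    The half-width is ``t_{1-(1-level)/2, n-2} * sqrt(sigma2 * (1/n +
    (x0 - xbar)^2 / Sxx))``; a noiseless fit yields a zero-width interval.
    """
    if not isinstance(model, CostTrend):
        raise InvalidParameterError("project() needs a fitted CostTrend")
    from scipy import stats

    point = model.predict(target_year)
    x0 = target_year - model.year_mean
    se_mean = np.sqrt(model.sigma2 * (1.0 / model.n + x0**2 / model.sxx))
    tcrit = stats.t.ppf(0.5 + level / 2.0, model.df_resid)
    half = float(tcrit * se_mean)
    return CostProjection(
        year=int(target_year), cost=point, ci=(point - half, point + half)
    )


def ppp_convert(amount_brl, factor: float):
    """Convert BRL amounts to international dollars: ``amount / factor``.

    Works elementwise on arrays; exactly invertible by multiplication.
    """
    if not (factor > 0):
        raise InvalidParameterError(f"PPP factor must be positive, got {factor}")
    arr = np.asarray(amount_brl, dtype=float) / factor
    return float(arr) if arr.ndim == 0 else arr


def load_cost_series(path) -> pd.DataFrame:
    """Read an annual cost series CSV with columns year, sex, cost_brl."""
    df = pd.read_csv(path)
    missing = [c for c in ("year", "sex", "cost_brl") if c not in df.columns]
    if missing:
        raise InvalidParameterError(f"cost series missing columns: {missing}")
    return df
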