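"""Turn raw sampling tables into equidistant, stationary, standardized series.

Missing observations are imputed with a shape-preserving (Fritsch-Carlson
monotone) piecewise-cubic Hermite interpolant, which also regrids the
irregular Mon/Wed/Fri calendar onto a uniform 123-point grid (step
284/122 = 2.33 days). Series are then detrended by an ordinary least squares
regression against time and divided by the population standard deviation of
the residuals, so that a standardized series has mean 0 and SD exactly 1 and
the mean forecast has an RMSE of exactly 1. The stored trend and scale allow
exact back-transformation of forecasts to the original scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .design import SamplingCalendar


class DegenerateSeriesError(ValueError):
    """Raised when residuals have zero variance (constant or pure-trend series)."""


@dataclass(frozen=True)
class TransformedSeries:
    """A detrended, standardized series with its back-transformation state.

    values are standardized residuals on the uniform grid; ``trend`` is the
    (intercept, slope-per-grid-index) OLS fit; ``scale`` the residual
    population SD used for standardization; ``window`` records whether the
    trend/scale were estimated on the full series or the training prefix.
    """

    values: np.ndarray
    grid_step: float
    trend: tuple[float, float]
    scale: float
    window: str
    original_mean: float

    @property
    def residuals(self) -> np.ndarray:
        """Detrended residuals before standardization."""
        return self.values * self.scale


def impute_and_regrid(date_offsets, values, missing=None,
                      calendar: SamplingCalendar | None = None) -> np.ndarray:
    """Impute missing points and interpolate onto the uniform sampling grid.

    Returns the series evaluated at ``calendar.n_dates`` equidistant points
    spanning [first, last] observed offsets. Leading/trailing missing values
    are extended with the nearest observed value before fitting (extrapolating
    cubics is unstable); interior observed points that coincide with grid
    points are reproduced exactly.
    """
    calendar = calendar or SamplingCalendar.default()
    t = np.asarray(date_offsets, dtype=float)
    x = np.asarray(values, dtype=float)
    if missing is None:
        miss = ~np.isfinite(x)
    else:
        miss = np.asarray(missing, dtype=bool) | ~np.isfinite(x)
    if miss.all():
        raise DegenerateSeriesError("all observations missing")
    obs_t = t[~miss]
    obs_x = x[~miss]
    if len(obs_x) < 4:
        raise ValueError(f"need >= 4 non-missing points, got {len(obs_x)}")
    # nearest-observed extension at the boundaries
    if t[0] < obs_t[0]:
        obs_t = np.concatenate([[t[0]], obs_t])
        obs_x = np.concatenate([[obs_x[0]], obs_x])
    if t[-1] > obs_t[-1]:
        obs_t = np.concatenate([obs_t, [t[-1]]])
        obs_x = np.concatenate([obs_x, [obs_x[-1]]])
    interp = PchipInterpolator(obs_t, obs_x)
    grid = np.linspace(t[0], t[-1], calendar.n_dates)
    return np.asarray(interp(grid), dtype=float)


def detrend_standardize(series, window: str = "full", n_train: int = 111) -> TransformedSeries:
    """Detrend (OLS against grid index) and standardize a regridded series.

    With ``window="full"`` the trend and scale use all points; with
    ``window="training_only"`` they use only the first ``n_train`` points and
    the fitted trend is extrapolated over the test window. The scale is the
    population SD (divide by n) of the window residuals, so a full-window
    standardized series has mean 0 and SD exactly 1.
    """
    x = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("series must be finite (impute first)")
    if window not in ("full", "training_only"):
        raise ValueError(f"unknown window {window!r}")
    n = len(x)
    t = np.arange(n, dtype=float)
    fit_n = n if window == "full" else int(n_train)
    tf, xf = t[:fit_n], x[:fit_n]
    slope, intercept = np.polyfit(tf, xf, 1)
    resid_fit = xf - (intercept + slope * tf)
    scale = float(np.sqrt(np.mean(resid_fit ** 2) - np.mean(resid_fit) ** 2))
    # guard: OLS residuals have zero mean, so this is just the population SD
    if scale <= 1e-12 * max(1.0, float(np.abs(xf).max())):
        raise DegenerateSeriesError("zero-variance residuals (constant or pure-trend series)")
    resid_all = x - (intercept + slope * t)
    return TransformedSeries(
        values=resid_all / scale,
        grid_step=SamplingCalendar.default().grid_step if n == 123 else 1.0,
        trend=(float(intercept), float(slope)),
        scale=scale,
        window=window,
        original_mean=float(np.mean(x)),
    )


def back_transform(forecast_values, transformed: TransformedSeries, indices) -> np.ndarray:
    """Map standardized-scale forecasts back to the original scale.

    prediction_orig(t) = forecast(t) * scale + intercept + slope * t; the
    exact inverse of detrend_standardize at every grid index.
    """
    f = np.asarray(forecast_values, dtype=float)
    idx = np.asarray(indices)
    n = len(transformed.values)
    if np.any(idx < 0) or np.any(idx >= n):
        raise IndexError("forecast index out of range")
    a, b = transformed.trend
    return f * transformed.scale + a + b * idx


def realized_richness(bottle_table: pd.DataFrame, members=None,
                      threshold: float = 0.0) -> float:
    """Median over sampling dates of the number of member taxa present.

    A taxon counts as present on a date when its (non-missing) abundance
    exceeds ``threshold``; missing observations do not count as present.
    The median of an even number of dates is the midpoint value.
    """
    from .simulate import AGGREGATE_VARIABLES

    taxa = bottle_table[~bottle_table["variable"].isin(AGGREGATE_VARIABLES)]
    if members is not None:
        taxa = taxa[taxa["variable"].isin(set(members))]
    if taxa.empty:
        return 0.0
    present = (taxa["value"] > threshold) & ~taxa["missing"].astype(bool)
    counts = present.groupby(taxa["date_offset"]).sum()
    return float(np.median(counts.to_numpy()))


def transform_table(raw: pd.DataFrame, calendar: SamplingCalendar | None = None,
                    window: str = "full", n_train: int = 111,
                    min_fraction_positive: float = 0.0):
    """Impute, regrid and standardize every (bottle, variable) series.

    Returns ``(long_df, transforms)`` where ``long_df`` has columns
    bottle_id/variable/t_index/value and ``transforms`` maps
    (bottle_id, variable) to its TransformedSeries. Series that are constant
    (degenerate) or extinct-flat are skipped.
    """
    calendar = calendar or SamplingCalendar.default()
    out = []
    transforms: dict[tuple[str, str], TransformedSeries] = {}
    for (bottle, var), grp in raw.groupby(["bottle_id", "variable"], sort=True):
        grp = grp.sort_values("date_offset")
        try:
            regridded = impute_and_regrid(grp["date_offset"], grp["value"],
                                          grp["missing"], calendar)
            if min_fraction_positive > 0:
                frac = np.mean(np.nan_to_num(grp["value"].to_numpy()) > 0)
                if frac < min_fraction_positive:
                    continue
            ts = detrend_standardize(regridded, window=window, n_train=n_train)
        except (DegenerateSeriesError, ValueError):
            continue
        transforms[(bottle, var)] = ts
        for i, v in enumerate(ts.values):
            out.append((bottle, var, i, v))
    long_df = pd.DataFrame(out, columns=["bottle_id", "variable", "t_index", "value"])
    return long_df, transforms
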