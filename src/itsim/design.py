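"""Pretreatment design matrices for the autoregressive count regression.

Each study year contributes the W days strictly before that year's
(possibly shifted) distribution day. Rows carry the response count, D
columns of lagged daily rates, six day-of-week dummies (Sunday is the
reference), a within-window linear trend shared across years, J-1 year
dummies (earliest study year is the reference) and a log-population offset.

The covariate builders (:class:`BaselineCovariates`,
:class:`SplineFourierCovariates`) know how to produce the fixed (non-lag)
covariate row for *any* calendar day, which is what lets the counterfactual
simulator extend trend, seasonality and calendar dummies past the treatment
day without duplicating the construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import patsy

from .ingest import AnalysisConfig, DailySeries, EventCalendar

__all__ = [
    "DesignMatrix",
    "BaselineCovariates",
    "SplineFourierCovariates",
    "compute_lagged_rates",
    "build_pretreatment_design",
]

_DOW_NAMES = ["Mon", "Tue", "Wed", "Thu", "Fri", "Sat"]  # Sunday = reference


def _dow_dummies(date: pd.Timestamp) -> np.ndarray:
    row = np.zeros(6)
    dow = date.dayofweek  # Monday=0 .. Sunday=6
    if dow < 6:
        row[dow] = 1.0
    return row


def _year_dummies(year: int, study_years: list[int]) -> np.ndarray:
    non_ref = study_years[1:]
    row = np.zeros(len(non_ref))
    if year in non_ref:
        row[non_ref.index(year)] = 1.0
    return row


class BaselineCovariates:
    """Fixed covariates of the base model: intercept, within-window trend,
    day-of-week dummies, year dummies.

    The trend is the integer day index within the W-day pretreatment window
    (1..W), centered at its midpoint, with the same construction every year;
    post-distribution day j continues it linearly at index W+1+j.
    """

    def __init__(self, window_days: int, study_years: list[int]):
        self.window_days = int(window_days)
        self.study_years = sorted(study_years)

    @property
    def columns(self) -> list[str]:
        return (
            ["intercept", "trend"]
            + [f"dow_{d}" for d in _DOW_NAMES]
            + [f"year_{y}" for y in self.study_years[1:]]
        )

    def row(self, date: pd.Timestamp, year: int, day_rel: int) -> np.ndarray:
        # day_rel counts days relative to the effective treatment day t0
        # (t0 = 0); window rows have day_rel in [-W, -1].
        trend = day_rel + (self.window_days + 1) / 2.0
        return np.concatenate(
            [[1.0, trend], _dow_dummies(date), _year_dummies(year, self.study_years)]
        )


class SplineFourierCovariates:
    """Fixed covariates of the extended model: natural cubic spline in
    calendar time plus annual Fourier harmonics, with the same day-of-week
    and year dummies as the base model.

    ``spline_df = 1`` degenerates to a plain linear calendar-time trend (in
    days, centered on the pretreatment rows) so the extended fit can be
    checked against the base model on identical rows. The spline basis is
    anchored on the pretreatment days and extrapolates linearly beyond its
    boundary knots, the natural-spline behaviour.
    """

    PERIOD = 365.25

    def __init__(
        self,
        pretreatment_dates: pd.DatetimeIndex,
        study_years: list[int],
        spline_df: int = 4,
        n_harmonics: int = 2,
    ):
        if spline_df == 2:
            raise ValueError("spline_df=2 is not a valid basis; use 1 (linear) or >= 3")
        if spline_df < 1:
            raise ValueError("spline_df must be >= 1")
        self.spline_df = int(spline_df)
        self.n_harmonics = int(n_harmonics)
        self.study_years = sorted(study_years)
        self.origin = pd.Timestamp(pretreatment_dates.min())
        x = self._x(pretreatment_dates)
        if spline_df == 1:
            self._center = float(x.mean())
            self._design_info = None
        else:
            # cr() is a partition of unity, so the raw basis spans the
            # constant; request one extra column and drop the first to stay
            # full-rank alongside the explicit intercept (spline_df columns
            # of trend flexibility beyond the constant).
            dm = patsy.dmatrix(
                f"cr(x, df={self.spline_df + 1}) - 1", {"x": x}, return_type="dataframe"
            )
            self._design_info = dm.design_info

    def _x(self, dates) -> np.ndarray:
        return (pd.DatetimeIndex(np.atleast_1d(dates)) - self.origin).days.to_numpy(
            dtype=float
        )

    @property
    def columns(self) -> list[str]:
        if self.spline_df == 1:
            spline = ["cal_trend"]
        else:
            spline = [f"spline_{i + 1}" for i in range(self.spline_df)]
        fourier = []
        for k in range(1, self.n_harmonics + 1):
            fourier += [f"sin_{k}", f"cos_{k}"]
        return (
            ["intercept"]
            + spline
            + fourier
            + [f"dow_{d}" for d in _DOW_NAMES]
            + [f"year_{y}" for y in self.study_years[1:]]
        )

    def _spline_block(self, x: np.ndarray) -> np.ndarray:
        if self.spline_df == 1:
            return (x - self._center)[:, None]
        raw = np.asarray(patsy.build_design_matrices([self._design_info], {"x": x})[0])
        return raw[:, 1:]

    def row(self, date: pd.Timestamp, year: int, day_rel: int) -> np.ndarray:
        x = self._x(pd.DatetimeIndex([date]))
        spline = self._spline_block(x)[0]
        angles = 2.0 * np.pi * np.arange(1, self.n_harmonics + 1) * x[0] / self.PERIOD
        fourier = np.ravel(np.column_stack([np.sin(angles), np.cos(angles)])) if self.n_harmonics else np.empty(0)
        return np.concatenate(
            [[1.0], spline, fourier, _dow_dummies(date), _year_dummies(year, self.study_years)]
        )


@dataclass
class DesignMatrix:
    """Stacked pretreatment rows for the NB regression.

    ``X`` holds the fixed covariates followed by the D lag columns (order
    recorded in ``columns``); ``offset`` is log population; ``row_meta``
    carries date, year and day-relative-to-t0 per row.
    """

    y: np.ndarray
    X: np.ndarray
    columns: list[str]
    offset: np.ndarray
    row_meta: pd.DataFrame
    lag_order: int
    covariates: object  # the fixed-covariate builder (row() + columns)

    def __post_init__(self) -> None:
        if np.isnan(self.X).any() or np.isnan(self.y).any():
            raise ValueError("design matrix contains missing values")

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @property
    def lag_columns(self) -> list[str]:
        return [c for c in self.columns if c.startswith("lag")]

    @property
    def fixed_columns(self) -> list[str]:
        return [c for c in self.columns if not c.startswith("lag")]

    def to_frame(self) -> pd.DataFrame:
        meta = self.row_meta.add_prefix("meta_").reset_index(drop=True)
        body = pd.DataFrame(self.X, columns=self.columns)
        return pd.concat(
            [meta, pd.Series(self.y, name="count"), pd.Series(self.offset, name="log_population"), body],
            axis=1,
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


def compute_lagged_rates(
    series: DailySeries,
    lag_order: int,
    dates: pd.DatetimeIndex,
    lag_covariate: str = "rate",
) -> pd.DataFrame:
    """Lag columns for the requested dates: column ``lag{d}`` at date t holds
    the observed daily rate (or count) at t−d.

    Lags draw on whatever observed days precede each date, including days
    before the modelling window, so no design rows are lost when those days
    exist in the series.
    """
    if lag_order < 1:
        raise ValueError("lag_order must be >= 1")
    dates = pd.DatetimeIndex(dates)
    values = pd.Series(
        series.rates if lag_covariate == "rate" else series.counts.astype(float),
        index=series.dates,
    )
    earliest_needed = dates.min() - pd.Timedelta(days=lag_order)
    if earliest_needed < series.dates[0]:
        earliest_usable = series.dates[0] + pd.Timedelta(days=lag_order)
        raise ValueError(
            f"insufficient preceding days for {lag_order} lags: earliest usable "
            f"date is {earliest_usable.date()}"
        )
    out = {}
    for d in range(1, lag_order + 1):
        out[f"lag{d}"] = values.reindex(dates - pd.Timedelta(days=d)).to_numpy()
    return pd.DataFrame(out, index=dates)


def window_dates(
    calendar: EventCalendar, config: AnalysisConfig, year: int
) -> tuple[pd.Timestamp, pd.DatetimeIndex]:
    """Effective treatment day and the W pretreatment days before it."""
    t0 = calendar.date_for(year) - pd.Timedelta(days=config.shift_days)
    W = config.pretreatment_window_days
    window = pd.date_range(t0 - pd.Timedelta(days=W), periods=W, freq="D")
    return t0, window


def build_pretreatment_design(
    series: DailySeries,
    calendar: EventCalendar,
    config: AnalysisConfig,
    lag_order: int,
    covariates: object | None = None,
    years: list[int] | None = None,
) -> DesignMatrix:
    """Stack the W-day pretreatment windows of all study years into one
    design matrix for the pooled fit.

    With ``config.lag_init == 'extend'`` (default) lag columns reach back to
    observed days immediately before each window, keeping all W rows per
    year; ``'drop'`` discards the first ``lag_order`` rows of each window
    instead.
    """
    calendar.validate_against(series)
    years = sorted(years if years is not None else calendar.study_years)
    covariates = covariates or BaselineCovariates(config.pretreatment_window_days, years)

    blocks, metas, lag_frames = [], [], []
    prev_t0: pd.Timestamp | None = None
    for year in years:
        t0, window = window_dates(calendar, config, year)
        if window[0] < series.dates[0] or window[-1] > series.dates[-1]:
            raise ValueError(
                f"pretreatment window {window[0].date()}..{window[-1].date()} for "
                f"year {year} extends outside the series span"
            )
        if prev_t0 is not None and window[0] <= prev_t0 + pd.Timedelta(days=config.horizon_days):
            warnings.warn(
                f"year {year}: pretreatment window overlaps the previous year's "
                "post-distribution horizon",
                stacklevel=2,
            )
        prev_t0 = t0
        use = window
        if lag_order > 0 and config.lag_init == "drop":
            use = window[lag_order:]
        day_rel = (use - t0).days.to_numpy()
        rows = np.vstack([covariates.row(d, year, dr) for d, dr in zip(use, day_rel)])
        if lag_order > 0:
            lag_frames.append(
                compute_lagged_rates(series, lag_order, use, config.lag_covariate)
            )
        blocks.append(rows)
        metas.append(
            pd.DataFrame({"date": use, "year": year, "day_rel": day_rel})
        )

    meta = pd.concat(metas, ignore_index=True)
    X = np.vstack(blocks)
    columns = list(covariates.columns)
    if lag_order > 0:
        lag = pd.concat(lag_frames)
        X = np.hstack([X, lag.to_numpy()])
        columns += list(lag.columns)
    sub = series.data.loc[meta["date"]]
    y = sub["count"].to_numpy(dtype=float)
    offset = np.log(sub["population"].to_numpy(dtype=float))
    return DesignMatrix(y, X, columns, offset, meta, lag_order, covariates)
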