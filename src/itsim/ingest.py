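"""Reading and validation of daily-count, population and configuration inputs.

The analysis consumes three kinds of delimited-text input:

* a daily event-count table — either pre-aggregated (``date,count``) or
  record-level (one row per event, with a ``date`` column and optional
  category/region columns used for subsetting, e.g. restricting deaths to
  unnatural causes or events to urban municipalities);
* an annual population table (``year,population``) used to express counts
  as rates per 10 000 residents and as the model's log-population offset;
* a flat YAML configuration holding the analysis parameters and the list of
  annual distribution (treatment) dates.
"""

from __future__ import annotations

import dataclasses
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DailySeries",
    "EventCalendar",
    "AnalysisConfig",
    "read_daily_counts",
    "read_population",
    "read_config",
    "attach_population",
]


@dataclass(frozen=True)
class DailySeries:
    """A gap-free daily count series for one outcome, with population joined.

    ``data`` is indexed by consecutive calendar days and carries integer
    ``count`` and (once attached) positive ``population`` columns; population
    is the annual statewide person count repeated on each day of its year.
    """

    data: pd.DataFrame
    outcome_label: str = "events"
    rate_denominator: float = 10_000.0

    def __post_init__(self) -> None:
        df = self.data
        if not isinstance(df.index, pd.DatetimeIndex):
            raise TypeError("DailySeries.data must be indexed by calendar dates")
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique()
            raise ValueError(f"duplicate dates in daily series: {list(dups[:5])}")
        if not df.index.is_monotonic_increasing:
            raise ValueError("dates must be strictly increasing")
        expected = pd.date_range(df.index[0], df.index[-1], freq="D")
        if len(expected) != len(df.index) or not (expected == df.index).all():
            raise ValueError("daily series has calendar gaps; zero-fill before constructing")
        counts = df["count"].to_numpy()
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integer-valued")
            object.__setattr__(self, "data", df.assign(count=counts.astype(np.int64)))
            df = self.data
        if (df["count"].to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if "population" in df.columns:
            pop = df["population"]
            if (pop <= 0).any():
                raise ValueError("population must be positive on every day")
            per_year = df.groupby(df.index.year)["population"].nunique()
            bad = per_year[per_year > 1]
            if len(bad):
                raise ValueError(f"population must be constant within a year; varies in {list(bad.index)}")

    # -- accessors -------------------------------------------------------
    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.data.index

    @property
    def counts(self) -> np.ndarray:
        return self.data["count"].to_numpy()

    @property
    def has_population(self) -> bool:
        return "population" in self.data.columns

    @property
    def population(self) -> np.ndarray:
        self._require_population()
        return self.data["population"].to_numpy(dtype=float)

    @property
    def rates(self) -> np.ndarray:
        """Daily event rates per ``rate_denominator`` residents."""
        self._require_population()
        return self.counts * self.rate_denominator / self.population

    def _require_population(self) -> None:
        if not self.has_population:
            raise ValueError(
                "no population attached to this DailySeries; use attach_population()"
            )

    def rate_on(self, date) -> float:
        date = pd.Timestamp(date)
        row = self.data.loc[date]
        return float(row["count"]) * self.rate_denominator / float(row["population"])

    def population_for_year(self, year: int) -> float:
        self._require_population()
        sub = self.data[self.data.index.year == year]
        if sub.empty:
            raise KeyError(f"year {year} not in series span")
        return float(sub["population"].iloc[0])

    def write_counts(self, path: str | Path) -> Path:
        """Write the ``date,count`` table; re-reading reproduces counts exactly."""
        path = Path(path)
        out = pd.DataFrame({"date": self.dates.strftime("%Y-%m-%d"), "count": self.counts})
        out.to_csv(path, index=False)
        return path

    def write_population(self, path: str | Path) -> Path:
        self._require_population()
        path = Path(path)
        years = self.data.index.year
        tbl = (
            self.data.assign(year=years)
            .groupby("year")["population"]
            .first()
            .reset_index()
        )
        tbl.to_csv(path, index=False)
        return path


@dataclass(frozen=True)
class EventCalendar:
    """The annual treatment days (one distribution date per study year)."""

    distribution_dates: Mapping[int, pd.Timestamp]
    holiday_dates: tuple = ()

    def __post_init__(self) -> None:
        dates = {}
        for year, d in dict(self.distribution_dates).items():
            ts = pd.Timestamp(d)
            if ts.year != int(year):
                raise ValueError(f"distribution date {ts.date()} filed under year {year}")
            dates[int(year)] = ts
        object.__setattr__(self, "distribution_dates", dates)
        object.__setattr__(
            self, "holiday_dates", tuple(pd.Timestamp(h) for h in self.holiday_dates)
        )

    @property
    def study_years(self) -> list[int]:
        return sorted(self.distribution_dates)

    def date_for(self, year: int) -> pd.Timestamp:
        return self.distribution_dates[year]

    def validate_against(self, series: DailySeries) -> None:
        lo, hi = series.dates[0], series.dates[-1]
        out = [d for d in self.distribution_dates.values() if not (lo <= d <= hi)]
        if out:
            raise ValueError(
                f"distribution dates outside series span {lo.date()}..{hi.date()}: "
                f"{[d.date() for d in out]}"
            )

    @classmethod
    def from_dates(cls, dates: Sequence, holiday_dates: Sequence = ()) -> "EventCalendar":
        stamps = [pd.Timestamp(d) for d in dates]
        years = [d.year for d in stamps]
        if len(set(years)) != len(years):
            raise ValueError("exactly one distribution date per study year required")
        return cls({d.year: d for d in stamps}, tuple(holiday_dates))


_CONFIG_DEFAULTS = dict(
    pretreatment_window_days=30,
    horizon_days=7,
    n_sims=1000,
    max_lag=7,
    lag_order="auto",
    shift_days=0,
    ci_level=0.95,
    seed=0,
    rate_denominator=10_000.0,
    lag_init="extend",
    lag_covariate="rate",
    lag_fill="recursive",
    pooling="drawwise",
    ljung_box_lags=7,
    ljung_box_adjust_df=True,
    per_year_fit=False,
)


@dataclass
class AnalysisConfig:
    """Tunable knobs of the pipeline, with the study's defaults.

    ``pretreatment_window_days`` (W) is the span of pre-distribution days
    each year's model rows come from; ``horizon_days`` (H) the number of
    post-distribution days beyond day 0; ``n_sims`` the number of simulated
    counterfactual trajectories; ``shift_days`` moves the effective
    treatment day earlier for anticipatory sensitivity runs.
    """

    pretreatment_window_days: int = 30
    horizon_days: int = 7
    n_sims: int = 1000
    max_lag: int = 7
    lag_order: int | str = "auto"
    shift_days: int = 0
    ci_level: float = 0.95
    seed: int = 0
    rate_denominator: float = 10_000.0
    lag_init: str = "extend"            # {extend, drop}: lag rows before the window
    lag_covariate: str = "rate"         # {rate, count}: scale of lagged regressors
    lag_fill: str = "recursive"         # {recursive, observed}: post-t0 lag source
    pooling: str = "drawwise"           # {drawwise, pairs}: year-pooling rule
    ljung_box_lags: int = 7
    ljung_box_adjust_df: bool = True
    per_year_fit: bool = False

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        W, H = self.pretreatment_window_days, self.horizon_days
        if W < self.max_lag + 8:
            raise ValueError(
                f"pretreatment_window_days={W} too small: need >= max_lag + 8 "
                f"= {self.max_lag + 8} rows to fit"
            )
        if not (0 < self.ci_level < 1):
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if self.n_sims < 2:
            raise ValueError(f"n_sims must be >= 2, got {self.n_sims}")
        if H < 1:
            raise ValueError(f"horizon_days must be >= 1, got {self.horizon_days}")
        if self.shift_days < 0:
            raise ValueError(f"shift_days must be >= 0, got {self.shift_days}")
        if self.lag_order != "auto":
            if not isinstance(self.lag_order, int) or self.lag_order < 0:
                raise ValueError("lag_order must be 'auto' or a non-negative integer")
        for key, allowed in [
            ("lag_init", {"extend", "drop"}),
            ("lag_covariate", {"rate", "count"}),
            ("lag_fill", {"recursive", "observed"}),
            ("pooling", {"drawwise", "pairs"}),
        ]:
            if getattr(self, key) not in allowed:
                raise ValueError(f"{key} must be one of {sorted(allowed)}")

    def replace(self, **kw) -> "AnalysisConfig":
        return dataclasses.replace(self, **kw)


def _parse_dates(raw: pd.Series, path: Path) -> pd.Series:
    parsed = pd.to_datetime(raw, errors="coerce", format="ISO8601")
    if parsed.isna().any():
        bad = parsed.index[parsed.isna()][0]
        raise ValueError(
            f"{path}: unparseable date {raw.loc[bad]!r} at data row {bad + 1}"
        )
    return parsed


def _apply_filters(df: pd.DataFrame, filters, path: Path) -> pd.DataFrame:
    if filters is None:
        return df
    if callable(filters):
        return df[filters(df)]
    for col, allowed in filters.items():
        if col not in df.columns:
            raise ValueError(f"{path}: filter column {col!r} not present")
        if isinstance(allowed, str):
            allowed = {allowed}
        df = df[df[col].isin(set(allowed))]
    return df


def read_daily_counts(
    path: str | Path,
    outcome_label: str = "events",
    filters: Mapping[str, object] | Callable[[pd.DataFrame], pd.Series] | None = None,
    population: Mapping[int, float] | str | Path | None = None,
    rate_denominator: float = 10_000.0,
    sep: str = ",",
) -> DailySeries:
    """Read a daily-count file into a gap-free :class:`DailySeries`.

    A ``count`` column selects pre-aggregated mode (one row per day); without
    it the file is treated as record-level (one row per event) and rows are
    aggregated by day after applying ``filters`` — a mapping from column name
    to allowed value(s), or a boolean predicate on the frame. Days absent
    after filtering are zero-filled over the file's full span.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=sep, dtype={"date": str})
    if "date" not in df.columns:
        raise ValueError(f"{path}: required column 'date' missing")
    dates = _parse_dates(df["date"], path)
    span = pd.date_range(dates.min(), dates.max(), freq="D")

    if "count" in df.columns:
        if df["date"].duplicated().any():
            dup = df["date"][df["date"].duplicated()].iloc[0]
            raise ValueError(f"{path}: duplicate date {dup} after aggregation")
        if (pd.to_numeric(df["count"]) < 0).any():
            raise ValueError(f"{path}: negative counts present")
        daily = pd.Series(
            pd.to_numeric(df["count"]).to_numpy(), index=pd.DatetimeIndex(dates)
        )
        if filters is not None:
            raise ValueError(
                f"{path}: category filters require record-level input, "
                "but a 'count' column marks this file as pre-aggregated"
            )
    else:
        recs = df.assign(date=dates)
        recs = _apply_filters(recs, filters, path)
        daily = recs.groupby("date").size()

    daily = daily.reindex(span, fill_value=0)
    data = pd.DataFrame({"count": daily.astype(np.int64)}, index=span)
    series = DailySeries(data, outcome_label, rate_denominator)
    if population is not None:
        if isinstance(population, (str, Path)):
            population = read_population(population)
        series = attach_population(series, population)
    return series


def read_population(path: str | Path, sep: str = ",") -> dict[int, float]:
    """Read the annual ``year,population`` table into a year→population map."""
    path = Path(path)
    df = pd.read_csv(path, sep=sep)
    for col in ("year", "population"):
        if col not in df.columns:
            raise ValueError(f"{path}: required column {col!r} missing")
    if (df["population"] <= 0).any():
        raise ValueError(f"{path}: population must be positive")
    if df["year"].duplicated().any():
        raise ValueError(f"{path}: duplicate years")
    return {int(y): float(p) for y, p in zip(df["year"], df["population"])}


def attach_population(series: DailySeries, population: Mapping[int, float]) -> DailySeries:
    """Join the annual population onto every day of a series."""
    years = sorted(set(series.dates.year))
    missing = [y for y in years if y not in population]
    if missing:
        raise ValueError(f"population table missing years required by series: {missing}")
    pop = np.array([population[y] for y in series.dates.year], dtype=float)
    return DailySeries(
        series.data.assign(population=pop), series.outcome_label, series.rate_denominator
    )


def read_config(path: str | Path) -> tuple[AnalysisConfig, EventCalendar, dict]:
    """Read the flat YAML run configuration.

    Returns the validated :class:`AnalysisConfig` (defaults applied for
    absent keys), the :class:`EventCalendar` built from ``distribution_dates``
    (and optional ``holiday_dates``), and a dict of the remaining keys
    (input paths, outcome label, scenario lists) for the caller.
    """
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    if "distribution_dates" not in raw:
        raise ValueError(f"{path}: required key 'distribution_dates' missing")
    calendar = EventCalendar.from_dates(
        raw.pop("distribution_dates"), raw.pop("holiday_dates", ())
    )
    kwargs = {k: raw.pop(k) for k in list(raw) if k in _CONFIG_DEFAULTS}
    try:
        config = AnalysisConfig(**kwargs)
    except ValueError as err:
        raise ValueError(f"{path}: invalid configuration: {err}") from err
    return config, calendar, raw
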