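"""Sensitivity and validation suite.

Four families of checks probe the design's assumptions:

* anticipatory shifts — re-run the pipeline with the treatment day moved
  1..14 days earlier, to detect pre-payment behaviour contaminating the
  pretreatment window;
* pretreatment-window sweep — alternative fitting windows (15..80 days);
* an extended pretreatment model using the full inter-distribution span
  with a natural cubic spline trend and annual Fourier harmonics;
* holiday power validation — dates with known injury spikes (New Year's
  Day, July 4th) stand in for the treatment day to confirm the design can
  flag real increases.

The 30-day post-distribution horizon robustness run is a config change
(``horizon_days=30``), not separate code.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import DesignMatrix, SplineFourierCovariates, compute_lagged_rates, window_dates
from .inference import DailyEffect, effects_table
from .ingest import AnalysisConfig, DailySeries, EventCalendar
from .model import FittedModel, fit_nb
from .pipeline import PipelineResult, analyze

__all__ = [
    "ScenarioResult",
    "SensitivityTable",
    "shifted_treatment_analysis",
    "window_sweep",
    "fit_extended_model",
    "extended_analysis",
    "holiday_power_check",
]

log = logging.getLogger(__name__)


@dataclass
class ScenarioResult:
    """One sensitivity scenario: its config delta and per-day effects."""

    label: str
    config_delta: dict
    effects: list[DailyEffect] = field(default_factory=list)
    failed: bool = False
    error: str | None = None
    result: PipelineResult | None = field(default=None, repr=False)


@dataclass
class SensitivityTable:
    """Collected scenarios plus a concordance summary."""

    scenarios: list[ScenarioResult]

    @property
    def fraction_with_significant_increase(self) -> float:
        ok = [s for s in self.scenarios if not s.failed]
        if not ok:
            return float("nan")
        hits = [
            any(e.significant and e.mean_diff > 0 for e in s.effects) for s in ok
        ]
        return float(np.mean(hits))

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for s in self.scenarios:
            if s.failed:
                frames.append(
                    pd.DataFrame({"scenario": [s.label], "failed": [1], "error": [s.error]})
                )
                continue
            f = effects_table(s.effects)
            f.insert(0, "scenario", s.label)
            f["failed"] = 0
            frames.append(f)
        return pd.concat(frames, ignore_index=True)


def _run_scenario(
    label: str,
    delta: dict,
    series: DailySeries,
    calendar: EventCalendar,
    config: AnalysisConfig,
) -> ScenarioResult:
    """Run one scenario with its prepared config; ``delta`` is the recorded
    departure from the baseline run (may name things outside AnalysisConfig,
    e.g. a placebo treatment date)."""
    try:
        res = analyze(series, calendar, config)
        return ScenarioResult(label, delta, res.effects, result=res)
    except ValueError as err:
        return ScenarioResult(label, delta, failed=True, error=f"{label}: {err}")


def shifted_treatment_analysis(
    series: DailySeries,
    calendar: EventCalendar,
    config: AnalysisConfig,
    shifts=range(1, 15),
) -> SensitivityTable:
    """Re-run the pipeline with the treatment day moved k days earlier.

    ``shift=0`` reproduces the baseline run exactly.
    """
    scenarios = [
        _run_scenario(
            f"shift={k}", {"shift_days": int(k)}, series, calendar,
            config.replace(shift_days=int(k)),
        )
        for k in shifts
    ]
    return SensitivityTable(scenarios)


def window_sweep(
    series: DailySeries,
    calendar: EventCalendar,
    config: AnalysisConfig,
    windows=(15, 30, 45, 60, 80),
) -> SensitivityTable:
    """Re-run the pipeline across alternative pretreatment window lengths."""
    seen, uniq = set(), []
    for w in windows:
        w = int(w)
        if w in seen:
            log.info("window_sweep: duplicate window %d requested; deduplicated", w)
            continue
        seen.add(w)
        uniq.append(w)
    scenarios = []
    for w in uniq:
        try:
            cfg = config.replace(pretreatment_window_days=w)
        except ValueError as err:
            scenarios.append(
                ScenarioResult(f"window={w}", {"pretreatment_window_days": w},
                               failed=True, error=f"window={w}: {err}")
            )
            continue
        scenarios.append(
            _run_scenario(f"window={w}", {"pretreatment_window_days": w},
                          series, calendar, cfg)
        )
    return SensitivityTable(scenarios)


def _extended_rows(
    series: DailySeries,
    calendar: EventCalendar,
    config: AnalysisConfig,
    lag_order: int,
    pretreatment: str,
) -> dict[int, pd.DatetimeIndex]:
    """Pretreatment dates per year for the extended model.

    ``'inter_distribution'``: from 30 days after the previous year's
    distribution date to the day before the current (effective) one; the
    first study year, having no predecessor, starts at the earliest date
    the lag columns allow. ``'window'``: the baseline W-day windows (used
    by the basis-equivalence check).
    """
    rows = {}
    years = calendar.study_years
    for i, year in enumerate(years):
        t0, window = window_dates(calendar, config, year)
        if pretreatment == "window":
            rows[year] = window
            continue
        if i == 0:
            start = series.dates[0] + pd.Timedelta(days=max(lag_order, 1))
        else:
            start = calendar.date_for(years[i - 1]) + pd.Timedelta(days=30)
        end = t0 - pd.Timedelta(days=1)
        if start > end:
            raise ValueError(
                f"year {year}: inter-distribution pretreatment span is empty"
            )
        rows[year] = pd.date_range(start, end, freq="D")
    return rows


def fit_extended_model(
    series: DailySeries,
    calendar: EventCalendar,
    config: AnalysisConfig,
    spline_df: int = 4,
    n_harmonics: int = 2,
    lag_order: int | None = None,
    pretreatment: str = "inter_distribution",
) -> tuple[FittedModel, DesignMatrix]:
    """Fit the spline+Fourier extended pretreatment model.

    Same NB-AR structure as the base model, but the within-window trend is
    replaced by a natural cubic spline over calendar time (``spline_df``
    basis columns; ``spline_df=1`` degenerates to a plain linear trend) plus
    ``n_harmonics`` annual sine/cosine pairs, and the pretreatment rows per
    year run from 30 days after the prior year's distribution date to the
    day before the current one.
    """
    calendar.validate_against(series)
    if lag_order is None:
        D = int(config.lag_order) if config.lag_order != "auto" else 1
    else:
        D = int(lag_order)
    rows = _extended_rows(series, calendar, config, D, pretreatment)
    all_dates = pd.DatetimeIndex(np.concatenate([r.to_numpy() for r in rows.values()]))
    covariates = SplineFourierCovariates(
        all_dates, calendar.study_years, spline_df=spline_df, n_harmonics=n_harmonics
    )

    blocks, metas, lag_frames = [], [], []
    for year, dates in rows.items():
        t0, _ = window_dates(calendar, config, year)
        day_rel = (dates - t0).days.to_numpy()
        blocks.append(
            np.vstack([covariates.row(d, year, dr) for d, dr in zip(dates, day_rel)])
        )
        if D:
            lag_frames.append(compute_lagged_rates(series, D, dates, config.lag_covariate))
        metas.append(pd.DataFrame({"date": dates, "year": year, "day_rel": day_rel}))

    meta = pd.concat(metas, ignore_index=True)
    X = np.vstack(blocks)
    columns = list(covariates.columns)
    if D:
        lag = pd.concat(lag_frames)
        X = np.hstack([X, lag.to_numpy()])
        columns += list(lag.columns)
    sub = series.data.loc[meta["date"]]
    dm = DesignMatrix(
        y=sub["count"].to_numpy(dtype=float),
        X=X,
        columns=columns,
        offset=np.log(sub["population"].to_numpy(dtype=float)),
        row_meta=meta,
        lag_order=D,
        covariates=covariates,
    )
    return fit_nb(dm), dm


def extended_analysis(
    series: DailySeries,
    calendar: EventCalendar,
    config: AnalysisConfig,
    spline_df: int = 4,
    n_harmonics: int = 2,
) -> ScenarioResult:
    """Run the full pipeline with the extended pretreatment model.

    Downstream simulation and inference are unchanged: the spline and
    Fourier covariates extend past the treatment day exactly as the base
    model's trend does.
    """
    from .counterfactual import draw_coefficients, observed_post_rates, simulate_trajectories
    from .inference import pool_across_years

    delta = {"spline_df": spline_df, "n_harmonics": n_harmonics}
    label = f"extended(df={spline_df},harmonics={n_harmonics})"
    try:
        D = int(config.lag_order) if config.lag_order != "auto" else 1
        model, _ = fit_extended_model(
            series, calendar, config, spline_df, n_harmonics, lag_order=D
        )
        draws = draw_coefficients(model, config.n_sims, config.seed)
        traj = simulate_trajectories(model, draws, series, calendar, config, config.seed)
        observed = observed_post_rates(series, calendar, config)
        effects = pool_across_years(observed, traj, config.ci_level, config.pooling)
        return ScenarioResult(label, delta, effects)
    except ValueError as err:
        return ScenarioResult(label, delta, failed=True, error=f"{label}: {err}")


def holiday_power_check(
    series: DailySeries,
    holiday_dates,
    config: AnalysisConfig,
) -> SensitivityTable:
    """Placebo-treatment power validation on known-spike holidays.

    Each holiday (a ``'MM-DD'`` string or any date whose month/day is
    taken) replaces the distribution day as t0 in every year of the series
    span that can accommodate the pretreatment window and horizon; the
    standard 30-day window ending the day before the holiday is reused.
    """
    scenarios = []
    for holiday in holiday_dates:
        if isinstance(holiday, str) and len(holiday) == 5:
            month, day = (int(p) for p in holiday.split("-"))
        else:
            ts = pd.Timestamp(holiday)
            month, day = ts.month, ts.day
        label = f"holiday={month:02d}-{day:02d}"
        lead = pd.Timedelta(days=config.pretreatment_window_days + config.max_lag + 1)
        dates = {}
        for year in sorted(set(series.dates.year)):
            t0 = pd.Timestamp(year=year, month=month, day=day)
            if (
                t0 - lead >= series.dates[0]
                and t0 + pd.Timedelta(days=config.horizon_days) <= series.dates[-1]
            ):
                dates[year] = t0
        if not dates:
            scenarios.append(
                ScenarioResult(label, {"t0": f"{month:02d}-{day:02d}"}, failed=True,
                               error=f"{label}: no year accommodates window and horizon")
            )
            continue
        cal = EventCalendar(dates)
        scenarios.append(
            _run_scenario(label, {"t0": f"{month:02d}-{day:02d}"}, series, cal, config)
        )
    return SensitivityTable(scenarios)
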