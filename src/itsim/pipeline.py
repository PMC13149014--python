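"""End-to-end orchestration: ingest → lag selection → fit → simulate → infer.

`analyze` is the single entry point the CLI, the sensitivity suite and the
calibration harness all share. Reproducibility contract: identical
(series, calendar, config — including seed) produce identical results;
coefficient draws and the per-year trajectory streams are derived from the
one root seed via distinct spawn keys.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .counterfactual import (
    TrajectoryDraws,
    draw_coefficients,
    observed_post_rates,
    simulate_trajectories,
)
from .design import BaselineCovariates, build_pretreatment_design
from .inference import DailyEffect, effect_estimates, effects_table, pool_across_years
from .ingest import AnalysisConfig, DailySeries, EventCalendar
from .model import DiagnosticsReport, FittedModel, LagSelection, diagnostics, fit_nb, select_lag_order

__all__ = ["PipelineResult", "analyze"]


@dataclass
class PipelineResult:
    """Everything a run produces, from the fitted model to the effect table."""

    effects: list[DailyEffect]
    per_year_effects: dict[int, list[DailyEffect]]
    model: FittedModel | dict[int, FittedModel]
    lag_order: int
    selection: LagSelection | None
    diagnostics: DiagnosticsReport
    observed: pd.DataFrame
    trajectories: TrajectoryDraws
    config: AnalysisConfig
    calendar: EventCalendar = field(repr=False, default=None)

    @property
    def table(self) -> pd.DataFrame:
        return effects_table(self.effects)


def _resolve_lag_order(
    series: DailySeries, calendar: EventCalendar, config: AnalysisConfig
) -> tuple[int, LagSelection | None]:
    if config.lag_order == "auto":
        sel = select_lag_order(series, calendar, config)
        return sel.order, sel
    return int(config.lag_order), None


def analyze(
    series: DailySeries, calendar: EventCalendar, config: AnalysisConfig
) -> PipelineResult:
    """Run the full interrupted-time-series pipeline on one outcome series.

    Fits the pooled pretreatment NB-AR model (or one per year when
    ``config.per_year_fit``), simulates ``config.n_sims`` counterfactual
    trajectories for days 0..H after each year's distribution date, and
    returns pooled and per-year observed-minus-expected effects with
    credible intervals.
    """
    calendar.validate_against(series)
    D, selection = _resolve_lag_order(series, calendar, config)
    observed = observed_post_rates(series, calendar, config)

    if not config.per_year_fit:
        dm = build_pretreatment_design(series, calendar, config, lag_order=D)
        model = fit_nb(dm)
        diag = diagnostics(model, dm, config)
        draws = draw_coefficients(model, config.n_sims, config.seed)
        traj = simulate_trajectories(model, draws, series, calendar, config, config.seed)
        fitted = model
    else:
        counts, rates, means, pops = {}, {}, {}, {}
        fitted = {}
        diag = None
        for year in calendar.study_years:
            cov = BaselineCovariates(config.pretreatment_window_days, [year])
            dm = build_pretreatment_design(
                series, calendar, config, lag_order=D, covariates=cov, years=[year]
            )
            m = fit_nb(dm)
            fitted[year] = m
            if diag is None:
                diag = diagnostics(m, dm, config)
            draws = draw_coefficients(m, config.n_sims, config.seed)
            sub_cal = EventCalendar({year: calendar.date_for(year)})
            t = simulate_trajectories(m, draws, series, sub_cal, config, config.seed)
            counts[year], rates[year], means[year] = (
                t.counts[year], t.rates[year], t.means[year],
            )
            pops[year] = t.populations[year]
        traj = TrajectoryDraws(
            days=observed.index.to_numpy(), counts=counts, rates=rates, means=means,
            populations=pops, seed=config.seed, rate_denominator=config.rate_denominator,
        )

    pooled = pool_across_years(observed, traj, config.ci_level, config.pooling)
    per_year = {}
    for year in calendar.study_years:
        sub = TrajectoryDraws(
            days=traj.days,
            counts={year: traj.counts[year]},
            rates={year: traj.rates[year]},
            means={year: traj.means[year]},
            populations={year: traj.populations[year]},
            seed=traj.seed,
            rate_denominator=traj.rate_denominator,
        )
        per_year[year] = effect_estimates(
            observed[year].to_numpy(), sub, config.ci_level, year=year
        )

    return PipelineResult(
        effects=pooled,
        per_year_effects=per_year,
        model=fitted,
        lag_order=D,
        selection=selection,
        diagnostics=diag,
        observed=observed,
        trajectories=traj,
        config=config,
        calendar=calendar,
    )
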