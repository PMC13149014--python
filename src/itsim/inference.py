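"""Observed-versus-counterfactual comparison and credible intervals.

For each post-distribution day j the per-draw difference
d_{s,j} = observed_j - simulated_{s,j} (rates per 10 000) is computed; the
effect estimate is its mean over draws and the 95% credible interval the
empirical 2.5% and 97.5% quantiles of {d_{s,j}} (type-7 linear-interpolation
quantiles; the rule is recorded in run metadata). A day is flagged
significant when the interval excludes zero. Study years are pooled
draw-wise: differences at the same draw index are averaged across years
before taking quantiles, so the pooled interval keeps the within-draw
dependence induced by the shared coefficient draw.

No multiplicity adjustment is applied across days: intervals are per-day,
as reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .counterfactual import TrajectoryDraws

__all__ = [
    "DailyEffect",
    "effect_estimates",
    "pool_across_years",
    "effects_table",
    "QUANTILE_METHOD",
]

QUANTILE_METHOD = "linear"  # numpy's type-7 empirical quantile


@dataclass(frozen=True)
class DailyEffect:
    """Observed-minus-expected rate difference for one post-distribution day."""

    day: int
    mean_diff: float
    ci_low: float
    ci_high: float
    significant: bool
    implied_count_diff: float

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError("ci_low must not exceed ci_high")


def _effects_from_diffs(
    diffs: np.ndarray, days: np.ndarray, ci_level: float, population: float,
    rate_denominator: float,
) -> list[DailyEffect]:
    lo_p, hi_p = (1.0 - ci_level) / 2.0, 1.0 - (1.0 - ci_level) / 2.0
    out = []
    for idx, day in enumerate(days):
        d = diffs[:, idx]
        lo, hi = np.quantile(d, [lo_p, hi_p], method=QUANTILE_METHOD)
        mean = float(d.mean())
        out.append(
            DailyEffect(
                day=int(day),
                mean_diff=mean,
                ci_low=float(lo),
                ci_high=float(hi),
                significant=bool(lo > 0.0 or hi < 0.0),
                implied_count_diff=mean * population / rate_denominator,
            )
        )
    return out


def effect_estimates(
    observed: np.ndarray,
    trajectories: TrajectoryDraws,
    ci_level: float = 0.95,
    year: int | None = None,
) -> list[DailyEffect]:
    """Per-day effects for a single year's observed rates versus its draws.

    ``observed`` holds rates for days 0..H; ``year`` defaults to the only
    year present in the trajectories.
    """
    years = trajectories.years
    if year is None:
        if len(years) != 1:
            raise ValueError("trajectories cover several years; pass `year` or pool")
        year = years[0]
    sims = trajectories.rates[year]
    observed = np.asarray(observed, dtype=float)
    if observed.shape[0] != sims.shape[1]:
        raise ValueError(
            f"observed covers {observed.shape[0]} days but trajectories have "
            f"{sims.shape[1]}"
        )
    diffs = observed[None, :] - sims
    return _effects_from_diffs(
        diffs, trajectories.days, ci_level, trajectories.populations[year],
        trajectories.rate_denominator,
    )


def pool_across_years(
    observed: pd.DataFrame,
    trajectories: TrajectoryDraws,
    ci_level: float = 0.95,
    pooling: str = "drawwise",
) -> list[DailyEffect]:
    """Pool per-year differences into one per-day effect series.

    ``observed`` is the day-by-year frame from
    :func:`itsim.counterfactual.observed_post_rates`. Draw-wise pooling
    (default) averages each draw index's differences across years; the
    ``'pairs'`` alternative stacks all year-draw differences into one pool.
    The implied statewide count difference uses the mean study-period
    population.
    """
    years = trajectories.years
    if sorted(observed.columns) != years:
        raise ValueError("observed and trajectories must cover identical years")
    n_sims = {trajectories.rates[y].shape[0] for y in years}
    if len(n_sims) != 1:
        raise ValueError("unequal draw counts across years; draws must be index-aligned")
    per_year = [
        observed[y].to_numpy()[None, :] - trajectories.rates[y] for y in years
    ]
    if pooling == "drawwise":
        diffs = np.mean(per_year, axis=0)
    elif pooling == "pairs":
        diffs = np.vstack(per_year)
    else:
        raise ValueError(f"unknown pooling rule {pooling!r}")
    mean_pop = float(np.mean([trajectories.populations[y] for y in years]))
    return _effects_from_diffs(
        diffs, trajectories.days, ci_level, mean_pop, trajectories.rate_denominator
    )


def effects_table(effects: list[DailyEffect]) -> pd.DataFrame:
    """Tabulate effects in the standard output layout."""
    return pd.DataFrame(
        {
            "day": [e.day for e in effects],
            "mean_diff": [e.mean_diff for e in effects],
            "ci_low": [e.ci_low for e in effects],
            "ci_high": [e.ci_high for e in effects],
            "significant": [int(e.significant) for e in effects],
            "implied_count_diff": [e.implied_count_diff for e in effects],
        }
    )


def write_effects(effects: list[DailyEffect], path: str | Path) -> Path:
    path = Path(path)
    effects_table(effects).to_csv(path, index=False, float_format="%.10g")
    return path


def plot_effects(effects: list[DailyEffect], ax=None, title: str | None = None):
    """Per-day mean differences with interval whiskers (headless-safe)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    days = [e.day for e in effects]
    means = [e.mean_diff for e in effects]
    lo = [e.mean_diff - e.ci_low for e in effects]
    hi = [e.ci_high - e.mean_diff for e in effects]
    ax.errorbar(days, means, yerr=[lo, hi], fmt="o", capsize=3, color="black")
    ax.axhline(0.0, lw=0.8, color="grey")
    ax.set_xlabel("days since distribution")
    ax.set_ylabel("observed − expected rate per 10 000")
    if title:
        ax.set_title(title)
    return ax
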