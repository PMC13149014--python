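"""Counterfactual trajectory simulation for the post-distribution horizon.

Uncertainty enters in two stages, mirroring a parametric bootstrap of the
fitted pretreatment model:

1. ``n_sims`` coefficient vectors are drawn from the multivariate normal
   with mean beta-hat and the fitted covariance matrix;
2. for each draw, expected means mu*_t are built for days 0..H after each
   year's distribution day and counts are sampled from NB2(mu*_t, theta-hat)
   via the gamma-Poisson mixture, with the dispersion fixed at its estimate.

Day 0 conditions on the observed pretreatment days through the lagged-rate
covariates; later days propagate each draw's own simulated rates
(counterfactual dynamics never condition on treated outcomes unless
``lag_fill='observed'`` is explicitly requested).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import window_dates
from .ingest import AnalysisConfig, DailySeries, EventCalendar
from .model import THETA_POISSON, FittedModel

__all__ = [
    "CoefficientDraws",
    "TrajectoryDraws",
    "draw_coefficients",
    "simulate_trajectories",
    "counts_to_rates",
    "observed_post_rates",
]

# Dynamic log-linear count simulation can, with very small probability, draw
# a coefficient vector whose rate feedback is supercritical; the trajectory
# then explodes within the horizon. Means are capped so sampling stays
# feasible; the empirical-quantile intervals are insensitive to the handful
# of capped draws.
_MU_MAX = 1e9


@dataclass
class CoefficientDraws:
    """``n_sims`` coefficient vectors drawn from MVN(beta-hat, vcov)."""

    values: np.ndarray  # (n_sims, p)
    columns: list[str]
    seed: int

    @property
    def n_sims(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.columns.index(name)]


@dataclass
class TrajectoryDraws:
    """Simulated counterfactual paths, one (n_sims, H+1) block per year."""

    days: np.ndarray                      # 0..H
    counts: dict[int, np.ndarray]
    rates: dict[int, np.ndarray]
    means: dict[int, np.ndarray] = field(repr=False)
    populations: dict[int, float] = field(default_factory=dict)
    seed: int = 0
    rate_denominator: float = 10_000.0

    @property
    def years(self) -> list[int]:
        return sorted(self.counts)

    @property
    def n_sims(self) -> int:
        return next(iter(self.counts.values())).shape[0]

    def save(self, path: str | Path) -> Path:
        """Persist to a compressed array container plus a JSON sidecar."""
        path = Path(path)
        arrays = {"days": self.days}
        for y in self.years:
            arrays[f"counts_{y}"] = self.counts[y]
            arrays[f"rates_{y}"] = self.rates[y]
            arrays[f"means_{y}"] = self.means[y]
        np.savez_compressed(path, **arrays)
        meta = {
            "seed": self.seed,
            "years": self.years,
            "populations": self.populations,
            "rate_denominator": self.rate_denominator,
            "n_sims": self.n_sims,
        }
        side = path.with_suffix(path.suffix + ".meta.json")
        side.write_text(json.dumps(meta, indent=2))
        return path


def draw_coefficients(
    model: FittedModel, n_sims: int, seed: int
) -> CoefficientDraws:
    """Draw coefficient vectors from MVN(beta-hat, vcov).

    Uses a symmetric eigendecomposition of the covariance so an exactly
    singular (even zero) matrix is valid; an eigenvalue materially below
    zero means the fit's information matrix was not positive semi-definite
    and the model should be refit.
    """
    beta = model.coefficients.to_numpy()
    V = model.vcov.to_numpy()
    evals, evecs = np.linalg.eigh(V)
    scale = max(float(evals.max()), 1.0)
    if evals.min() < -1e-8 * scale:
        raise ValueError(
            f"vcov has negative eigenvalue {evals.min():.3e}; refit the model"
        )
    root = evecs * np.sqrt(np.clip(evals, 0.0, None))
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    z = rng.standard_normal((n_sims, len(beta)))
    return CoefficientDraws(beta[None, :] + z @ root.T, list(model.coefficients.index), seed)


def counts_to_rates(
    counts: np.ndarray, population: float, rate_denominator: float = 10_000.0
) -> np.ndarray:
    """Convert counts to rates per ``rate_denominator`` residents, elementwise."""
    if population <= 0:
        raise ValueError("population must be positive")
    return np.asarray(counts, dtype=float) * rate_denominator / population


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, theta: float) -> np.ndarray:
    """NB2 sampling via the gamma-Poisson mixture (Poisson when theta is huge)."""
    if theta >= THETA_POISSON:
        return rng.poisson(mu)
    lam = np.minimum(rng.gamma(theta, mu / theta), _MU_MAX)
    return rng.poisson(lam)


def observed_post_rates(
    series: DailySeries, calendar: EventCalendar, config: AnalysisConfig
) -> pd.DataFrame:
    """Observed rates for days 0..H after each year's effective treatment day.

    Returns a frame indexed by day 0..H with one column per study year.
    """
    H = config.horizon_days
    out = {}
    for year in calendar.study_years:
        t0, _ = window_dates(calendar, config, year)
        days = pd.date_range(t0, periods=H + 1, freq="D")
        if days[-1] > series.dates[-1]:
            raise ValueError(
                f"horizon day {days[-1].date()} extends past the series span "
                f"({series.dates[-1].date()})"
            )
        sub = series.data.loc[days]
        out[year] = (
            sub["count"].to_numpy() * config.rate_denominator
            / sub["population"].to_numpy()
        )
    return pd.DataFrame(out, index=np.arange(H + 1))


def simulate_trajectories(
    model: FittedModel,
    draws: CoefficientDraws,
    series: DailySeries,
    calendar: EventCalendar,
    config: AnalysisConfig,
    seed: int,
) -> TrajectoryDraws:
    """Simulate counterfactual count/rate paths for days 0..H of each year.

    Per draw s and day j: mu*_j = exp(x_j' beta*_s + log P_year), with the
    day's calendar covariates (day of week, trend continuation, year dummy)
    taken from the true post-distribution calendar and the lagged-rate
    covariates taken from observed pretreatment days where the lag reaches
    before day 0 and from the draw's own simulated history otherwise
    (``config.lag_fill='recursive'``). Counts are NB2(mu*, theta-hat).

    Each year uses an independent RNG stream derived from ``seed`` and the
    year's index, so results are reproducible regardless of execution order.
    """
    H, D = config.horizon_days, model.lag_order
    n_sims = draws.n_sims
    fixed_cols = [c for c in model.columns if not c.startswith("lag")]
    lag_cols = [f"lag{d}" for d in range(1, D + 1)]
    beta_fixed = draws.values[:, [draws.columns.index(c) for c in fixed_cols]]
    beta_lag = (
        draws.values[:, [draws.columns.index(c) for c in lag_cols]]
        if D
        else np.zeros((n_sims, 0))
    )

    counts: dict[int, np.ndarray] = {}
    rates: dict[int, np.ndarray] = {}
    means: dict[int, np.ndarray] = {}
    pops: dict[int, float] = {}
    for yi, year in enumerate(calendar.study_years):
        t0, _ = window_dates(calendar, config, year)
        days = pd.date_range(t0, periods=H + 1, freq="D")
        if days[-1] > series.dates[-1]:
            raise ValueError(
                f"horizon day {days[-1].date()} extends past the series span"
            )
        P = series.population_for_year(year)
        pops[year] = P
        fixed = np.vstack(
            [model.covariates.row(d, year, j) for j, d in enumerate(days)]
        )  # (H+1, p_fixed)
        eta_fixed = beta_fixed @ fixed.T + np.log(P)  # (n_sims, H+1)

        # lag history: rates at t0-1, t0-2, ... shared by all draws at day 0
        if D:
            hist_dates = [t0 - pd.Timedelta(days=d) for d in range(1, D + 1)]
            obs_hist = np.array([series.rate_on(d) for d in hist_dates])
            history = np.tile(obs_hist, (n_sims, 1))  # (n_sims, D), col d-1 = lag d
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(yi,)))

        c = np.empty((n_sims, H + 1), dtype=np.int64)
        m = np.empty((n_sims, H + 1))
        for j in range(H + 1):
            eta = eta_fixed[:, j].copy()
            if D:
                eta += np.einsum("sd,sd->s", beta_lag, history)
            mu = np.minimum(np.exp(np.minimum(eta, np.log(_MU_MAX))), _MU_MAX)
            m[:, j] = mu
            c[:, j] = _nb_sample(rng, mu, model.theta)
            if D:
                if config.lag_fill == "recursive":
                    new_rate = c[:, j] * config.rate_denominator / P
                else:  # observed post-t0 data (leaks treatment; off by default)
                    new_rate = np.full(n_sims, series.rate_on(days[j]))
                history = np.column_stack([new_rate, history[:, :-1]])
        counts[year] = c
        rates[year] = counts_to_rates(c, P, config.rate_denominator)
        means[year] = m

    return TrajectoryDraws(
        days=np.arange(H + 1),
        counts=counts,
        rates=rates,
        means=means,
        populations=pops,
        seed=seed,
        rate_denominator=config.rate_denominator,
    )
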