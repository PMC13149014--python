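import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import itsim
from itsim import (
    AnalysisConfig,
    EventCalendar,
    counts_to_rates,
    draw_coefficients,
    observed_post_rates,
    simulate_trajectories,
)
from itsim.design import BaselineCovariates
from itsim.model import FittedModel

from conftest import make_series


def toy_model(intercept, lag_coef=None, theta=1e9, vcov_scale=0.0, year=2015, W=30):
    cov = BaselineCovariates(W, [year])
    columns = list(cov.columns) + (["lag1"] if lag_coef is not None else [])
    beta = pd.Series(0.0, index=columns)
    beta["intercept"] = intercept
    if lag_coef is not None:
        beta["lag1"] = lag_coef
    V = pd.DataFrame(vcov_scale * np.eye(len(columns)), index=columns, columns=columns)
    return FittedModel(
        coefficients=beta, vcov=V, theta=theta, log_likelihood=0.0, aic=0.0,
        n_obs=W, lag_order=0 if lag_coef is None else 1, converged=True,
        covariates=cov,
    )


@pytest.fixture()
def flat_series():
    # 2015 with constant counts; population 10 000 so rate == count
    return make_series([10] * 365, start="2015-01-01", population=10_000.0)


@pytest.fixture()
def cal2015():
    return EventCalendar.from_dates(["2015-10-01"])


class TestCoefficientDraws:
    def test_zero_vcov_draws_collapse_to_estimate(self):
        m = toy_model(intercept=np.log(10 / 1e4))
        draws = draw_coefficients(m, 50, seed=1)
        assert np.array_equal(draws.values, np.tile(m.coefficients.to_numpy(), (50, 1)))

    def test_requested_number_of_draws(self, result3):
        draws = draw_coefficients(result3.model, 1000, seed=2)
        assert draws.values.shape == (1000, len(result3.model.coefficients))

    def test_sample_variance_matches_vcov(self):
        cols = ["intercept"]
        m = FittedModel(
            coefficients=pd.Series([0.0], index=cols),
            vcov=pd.DataFrame([[4.0]], index=cols, columns=cols),
            theta=10.0, log_likelihood=0.0, aic=0.0, n_obs=10, lag_order=0,
            converged=True,
        )
        draws = draw_coefficients(m, 100_000, seed=3)
        assert draws.values.var() == pytest.approx(4.0, rel=0.05)

    def test_negative_eigenvalue_rejected(self):
        cols = ["a", "b"]
        m = FittedModel(
            coefficients=pd.Series([0.0, 0.0], index=cols),
            vcov=pd.DataFrame([[1.0, 2.0], [2.0, 1.0]], index=cols, columns=cols),
            theta=10.0, log_likelihood=0.0, aic=0.0, n_obs=10, lag_order=0,
            converged=True,
        )
        with pytest.raises(ValueError, match="refit"):
            draw_coefficients(m, 10, seed=0)


class TestCountsToRates:
    def test_reference_values(self):
        assert counts_to_rates(11, 110_000.0) == pytest.approx(1.0)
        assert counts_to_rates(0, 5_000.0) == 0.0

    @given(st.integers(0, 10_000), st.floats(1e3, 1e7))
    def test_proportionality(self, count, pop):
        assert counts_to_rates(count, pop) == pytest.approx(count * 1e4 / pop)

    def test_matrix_shape_preserved(self):
        m = np.arange(12).reshape(3, 4)
        out = counts_to_rates(m, 10_000.0)
        assert out.shape == (3, 4)
        assert np.allclose(out, m.astype(float))


class TestSimulateTrajectories:
    def test_horizon_gives_h_plus_one_columns(self, result3, config_fast):
        assert result3.trajectories.rates[2009].shape == (config_fast.n_sims, 8)
        assert list(result3.trajectories.days) == list(range(8))

    def test_identical_seeds_bit_identical(self, result3, series3, mortality_params3, config_fast):
        draws = draw_coefficients(result3.model, 100, seed=7)
        a = simulate_trajectories(result3.model, draws, series3,
                                  mortality_params3.calendar, config_fast, seed=9)
        b = simulate_trajectories(result3.model, draws, series3,
                                  mortality_params3.calendar, config_fast, seed=9)
        for y in a.years:
            assert np.array_equal(a.counts[y], b.counts[y])
            assert np.array_equal(a.rates[y], b.rates[y])

    def test_degenerate_limit_reduces_to_plugin_poisson_mean(self, flat_series, cal2015):
        # vcov = 0, no AR terms, theta -> inf: every draw is Poisson(mu-hat)
        m = toy_model(intercept=np.log(10 / 1e4))
        cfg = AnalysisConfig(seed=0, lag_order=0, n_sims=4000)
        draws = draw_coefficients(m, cfg.n_sims, seed=1)
        traj = simulate_trajectories(m, draws, flat_series, cal2015, cfg, seed=2)
        mu = traj.means[2015]
        assert np.allclose(mu, 10.0)
        day0 = traj.counts[2015][:, 0]
        assert day0.mean() == pytest.approx(10.0, abs=3 * np.sqrt(10 / cfg.n_sims))

    def test_recursive_and_observed_lag_fill_agree_without_ar(self, flat_series, cal2015):
        m = toy_model(intercept=np.log(10 / 1e4), lag_coef=0.0, theta=12.0)
        draws = draw_coefficients(m, 500, seed=4)
        out = {}
        for fill in ("recursive", "observed"):
            cfg = AnalysisConfig(seed=0, lag_order=1, n_sims=500, lag_fill=fill)
            out[fill] = simulate_trajectories(m, draws, flat_series, cal2015, cfg, seed=5)
        assert np.array_equal(out["recursive"].counts[2015], out["observed"].counts[2015])

    def test_overdispersion_preserved(self, flat_series, cal2015):
        m = toy_model(intercept=np.log(10 / 1e4), theta=3.0)
        cfg = AnalysisConfig(seed=0, lag_order=0, n_sims=4000)
        draws = draw_coefficients(m, cfg.n_sims, seed=1)
        traj = simulate_trajectories(m, draws, flat_series, cal2015, cfg, seed=3)
        day0 = traj.counts[2015][:, 0]
        assert day0.var() > day0.mean()
        # NB2: variance should be near mu + mu^2/theta = 10 + 100/3
        assert day0.var() == pytest.approx(10 + 100 / 3.0, rel=0.15)

    def test_horizon_past_series_span_rejected(self, flat_series):
        cal = EventCalendar.from_dates(["2015-12-28"])
        m = toy_model(intercept=np.log(10 / 1e4))
        cfg = AnalysisConfig(seed=0, lag_order=0, n_sims=10)
        draws = draw_coefficients(m, 10, seed=0)
        with pytest.raises(ValueError, match="span"):
            simulate_trajectories(m, draws, flat_series, cal, cfg, seed=0)


def test_observed_post_rates_layout(series3, mortality_params3, config_fast):
    obs = observed_post_rates(series3, mortality_params3.calendar, config_fast)
    assert list(obs.index) == list(range(8))
    assert sorted(obs.columns) == mortality_params3.calendar.study_years
    year = mortality_params3.calendar.study_years[0]
    t0 = mortality_params3.calendar.date_for(year)
    assert obs.loc[0, year] == pytest.approx(series3.rate_on(t0))
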