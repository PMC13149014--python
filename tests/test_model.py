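import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from itsim import AnalysisConfig, generate_series, ljung_box_test, select_lag_order
from itsim.design import DesignMatrix
from itsim.model import fit_nb, pearson_residuals

from conftest import nb2_loglik


def plain_design(y, X, columns, offset=None):
    y = np.asarray(y, dtype=float)
    offset = np.zeros(len(y)) if offset is None else np.asarray(offset, dtype=float)
    meta = pd.DataFrame(
        {"date": pd.date_range("2015-01-01", periods=len(y)), "year": 2015,
         "day_rel": np.arange(len(y)) - len(y)}
    )
    return DesignMatrix(y, np.asarray(X, float), list(columns), offset, meta, 0, None)


class TestFitNB:
    def test_intercept_only_recovers_sample_mean(self):
        # constant counts: the saturated intercept model must hit the mean exactly
        y = np.full(40, 5.0)
        dm = plain_design(y, np.ones((40, 1)), ["intercept"], offset=np.log(np.full(40, 1e4)))
        fit = fit_nb(dm)
        assert np.exp(fit.coefficients["intercept"]) * 1e4 == pytest.approx(5.0, rel=1e-4)

    def test_poisson_generated_data_gives_large_theta_and_poisson_betas(self):
        rng = np.random.default_rng(3)
        n = 400
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        mu = np.exp(2.0 + 0.3 * X[:, 1])
        y = rng.poisson(mu)
        dm = plain_design(y, X, ["intercept", "x"])
        fit = fit_nb(dm)
        pois = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        se = np.sqrt(np.diag(pois.cov_params()))
        # equidispersed data: theta large (variance inflation mu/theta ~ 0.1)
        assert fit.theta > 20
        assert np.all(np.abs(fit.coefficients.to_numpy() - pois.params) < 2 * se)

    def test_vcov_symmetric_positive_semidefinite(self, result3):
        V = result3.model.vcov.to_numpy()
        assert np.allclose(V, V.T)
        assert np.linalg.eigvalsh(V).min() > -1e-10

    def test_estimate_is_local_maximum(self):
        rng = np.random.default_rng(9)
        n = 200
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        mu = np.exp(1.2 + 0.5 * X[:, 1])
        y = rng.poisson(rng.gamma(4.0, mu / 4.0))
        dm = plain_design(y, X, ["intercept", "x"])
        fit = fit_nb(dm)
        beta = fit.coefficients.to_numpy()
        ll_hat = nb2_loglik(y, np.exp(X @ beta), fit.theta)
        for eps in (1e-3, 1e-2):
            for k in range(len(beta)):
                for sign in (-1, 1):
                    b = beta.copy()
                    b[k] += sign * eps
                    assert nb2_loglik(y, np.exp(X @ b), fit.theta) <= ll_hat + 1e-9

    def test_predicted_means_positive(self, result3, series3, mortality_params3, config_fast):
        from itsim.design import build_pretreatment_design

        dm = build_pretreatment_design(
            series3, mortality_params3.calendar, config_fast, result3.lag_order
        )
        assert (result3.model.predicted_means(dm) > 0).all()

    def test_collinear_columns_named(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        X = np.column_stack([np.ones(50), x, 2 * x])
        y = rng.poisson(np.exp(1 + 0.1 * x))
        dm = plain_design(y, X, ["intercept", "x", "x_twice"])
        with pytest.raises(ValueError, match="collinear"):
            fit_nb(dm)

    def test_too_few_rows_rejected(self):
        dm = plain_design([1, 2, 3], np.ones((3, 2)) * [[1, 0], [1, 1], [1, 2]],
                          ["intercept", "x"])
        with pytest.raises(ValueError, match="too few rows"):
            fit_nb(dm)


class TestLjungBox:
    def test_alternating_residuals_match_hand_formula(self):
        n = 100
        resid = np.tile([1.0, -1.0], n // 2)
        q, p = ljung_box_test(resid, 1)
        # rho_1 ~ -1 so Q ~ n(n+2)/(n-1)
        assert q == pytest.approx(n * (n + 2) / (n - 1), rel=0.02)
        assert p < 1e-10

    def test_constructed_zero_autocorrelation(self):
        # orthogonal-by-construction: lag-1 products cancel in pairs
        resid = np.tile([1.0, 1.0, -1.0, -1.0], 25)
        rho1 = np.corrcoef(resid[:-1], resid[1:])[0, 1]
        assert abs(rho1) < 0.03
        q, p = ljung_box_test(resid, 1)
        assert q < 0.2
        assert p > 0.6

    def test_constant_residuals_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            ljung_box_test(np.ones(50), 3)

    def test_df_adjustment_moves_pvalue(self):
        rng = np.random.default_rng(5)
        resid = rng.normal(size=200)
        q0, p0 = ljung_box_test(resid, 7, model_df=0)
        q1, p1 = ljung_box_test(resid, 7, model_df=2)
        assert q0 == pytest.approx(q1)
        assert p1 < p0  # fewer df, same Q

    def test_null_rejection_rate_near_nominal(self):
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 400
        for _ in range(reps):
            _, p = ljung_box_test(rng.normal(size=150), 7)
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.03)


class TestLagSelection:
    def test_selected_order_bounded_by_max_lag(self, series3, mortality_params3):
        cfg = AnalysisConfig(seed=0, max_lag=2, lag_order="auto")
        sel = select_lag_order(series3, mortality_params3.calendar, cfg)
        assert 0 <= sel.order <= 2
        assert sel.diagnostics.ljung_box_pvalue >= 0

    def test_independent_days_rarely_select_lags(self, mortality_params3):
        # white-noise generator: lag-1 should win only at AIC's overfitting rate
        params = mortality_params3.replace(ar_coefficients=())
        cfg = AnalysisConfig(seed=0, max_lag=3, lag_order="auto")
        picked = []
        for seed in range(25):
            series = generate_series(params, seed=seed)
            picked.append(select_lag_order(series, params.calendar, cfg).order)
        # chi2(1) > 2 has probability ~0.157 under the null
        assert np.mean(np.asarray(picked) >= 1) < 0.45

    def test_pearson_residuals_standardized(self, result3, series3, mortality_params3, config_fast):
        from itsim.design import build_pretreatment_design

        dm = build_pretreatment_design(
            series3, mortality_params3.calendar, config_fast, result3.lag_order
        )
        r = pearson_residuals(result3.model, dm)
        assert abs(r.mean()) < 0.3
        assert 0.5 < r.std() < 2.0
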