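"""Autoregressive negative-binomial estimation and diagnostics.

The pretreatment model is an NB2 count regression with a log link and a
log-population offset:

    log E[Y_t | X] = b0 + b1*t + sum_d b_d * rate_{t-d} + dow + year,
    Var[Y_t] = mu_t + mu_t^2 / theta,

fit by joint maximum likelihood over (beta, theta). Coefficient uncertainty
for the counterfactual simulation is summarised by the beta block of the
inverse observed information; theta is treated as fixed at its estimate
downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from statsmodels.discrete.discrete_model import NegativeBinomial
from statsmodels.stats.diagnostic import acorr_ljungbox

from .design import DesignMatrix, build_pretreatment_design
from .ingest import AnalysisConfig, DailySeries, EventCalendar

__all__ = [
    "FittedModel",
    "DiagnosticsReport",
    "LagSelection",
    "fit_nb",
    "select_lag_order",
    "ljung_box_test",
    "pearson_residuals",
]

# theta above this is numerically Poisson; simulation switches distributions
THETA_POISSON = 1e7


@dataclass
class FittedModel:
    """MLE of the NB2 pretreatment regression.

    ``coefficients`` are the regression betas (no dispersion entry);
    ``vcov`` is their covariance block; ``theta`` the NB2 size parameter
    (variance = mu + mu^2/theta, so larger theta means closer to Poisson).
    """

    coefficients: pd.Series
    vcov: pd.DataFrame
    theta: float
    log_likelihood: float
    aic: float
    n_obs: int
    lag_order: int
    converged: bool
    covariates: object = None  # fixed-covariate builder carried from the design
    method: str = "joint-mle"

    def __post_init__(self) -> None:
        V = self.vcov.to_numpy()
        if not np.allclose(V, V.T, atol=1e-8 * (1 + np.abs(V).max())):
            raise ValueError("vcov must be symmetric")
        if self.theta <= 0:
            raise ValueError("dispersion theta must be positive")

    @property
    def columns(self) -> list[str]:
        return list(self.coefficients.index)

    def linear_predictor(self, X: np.ndarray, offset: np.ndarray) -> np.ndarray:
        return X @ self.coefficients.to_numpy() + offset

    def predicted_means(self, design: DesignMatrix) -> np.ndarray:
        return np.exp(self.linear_predictor(design.X, design.offset))

    def summary_frame(self) -> pd.DataFrame:
        se = np.sqrt(np.diag(self.vcov.to_numpy()))
        return pd.DataFrame(
            {"estimate": self.coefficients, "std_error": se}
        ).assign(z=lambda f: f["estimate"] / f["std_error"])


@dataclass
class DiagnosticsReport:
    """Residual diagnostics of a fitted model."""

    ljung_box_stat: float
    ljung_box_pvalue: float
    ljung_box_lags: int
    pearson_residuals: np.ndarray = field(repr=False)
    overdispersion_ratio: float = float("nan")


@dataclass
class LagSelection:
    """Outcome of the forward stepwise autoregressive-order search."""

    order: int
    aic_by_order: dict[int, float]
    model: FittedModel
    diagnostics: DiagnosticsReport

    def __int__(self) -> int:
        return self.order


def _check_rank(X: np.ndarray, columns: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name a minimal set of columns that completes the deficiency
        _, R = np.linalg.qr(X)
        diag = np.abs(np.diag(R))
        bad = [columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")


def _profiled_fallback(y, X, offset, start_beta):
    """Outer 1-D optimisation of the dispersion with an IRLS inner fit."""

    def neg_profile_ll(log_alpha: float) -> float:
        fam = sm.families.NegativeBinomial(alpha=np.exp(log_alpha))
        res = sm.GLM(y, X, family=fam, offset=offset).fit(start_params=start_beta)
        return -res.llf

    opt = optimize.minimize_scalar(
        neg_profile_ll, bounds=(np.log(1e-8), np.log(1e4)), method="bounded",
        options={"xatol": 1e-8},
    )
    alpha = float(np.exp(opt.x))
    fam = sm.families.NegativeBinomial(alpha=alpha)
    res = sm.GLM(y, X, family=fam, offset=offset).fit(start_params=start_beta)
    return res, alpha, -opt.fun


def fit_nb(design: DesignMatrix) -> FittedModel:
    """Fit the NB2 regression by maximum likelihood.

    Starts from a Poisson fit, maximises the joint (beta, theta) likelihood
    quasi-Newton with analytic gradients, and falls back to a
    profiled-dispersion outer optimisation if the joint fit fails to
    converge. Near-zero estimated overdispersion is clamped to an
    effectively-Poisson ``theta`` of 1e7.
    """
    y, X, offset = design.y, design.X, design.offset
    if design.n_obs <= X.shape[1] + 1:
        raise ValueError(
            f"too few rows ({design.n_obs}) for {X.shape[1]} coefficients"
        )
    _check_rank(X, design.columns)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        poisson = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        start = np.r_[poisson.params, 0.05]
        model = NegativeBinomial(y, X, loglike_method="nb2", offset=offset)
        converged, res = False, None
        for method in ("bfgs", "nm"):
            try:
                res = model.fit(start_params=start, method=method, maxiter=500, disp=0)
                converged = bool(res.mle_retvals.get("converged", False))
            except Exception:
                res = None
            if converged and res is not None and np.isfinite(res.params).all():
                break
            converged = False

    if converged and res is not None:
        alpha = max(float(res.params[-1]), 0.0)
        beta = np.asarray(res.params[:-1], dtype=float)
        V = np.asarray(res.cov_params())[:-1, :-1]
        llf, method_used = float(res.llf), "joint-mle"
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            glm_res, alpha, llf = _profiled_fallback(y, X, offset, poisson.params)
        beta = np.asarray(glm_res.params, dtype=float)
        V = np.asarray(glm_res.cov_params())
        converged, method_used = True, "profiled-dispersion"
        if not np.isfinite(beta).all():
            raise RuntimeError(
                "negative binomial fit failed to converge after the "
                "profiled-dispersion fallback"
            )

    theta = 1.0 / alpha if alpha > 1.0 / THETA_POISSON else THETA_POISSON
    V = 0.5 * (V + V.T)
    k = len(beta) + 1  # betas + dispersion
    return FittedModel(
        coefficients=pd.Series(beta, index=design.columns),
        vcov=pd.DataFrame(V, index=design.columns, columns=design.columns),
        theta=theta,
        log_likelihood=llf,
        aic=2.0 * k - 2.0 * llf,
        n_obs=design.n_obs,
        lag_order=design.lag_order,
        converged=converged,
        covariates=design.covariates,
        method=method_used,
    )


def pearson_residuals(model: FittedModel, design: DesignMatrix) -> np.ndarray:
    mu = model.predicted_means(design)
    var = mu + mu**2 / model.theta
    return (design.y - mu) / np.sqrt(var)


def diagnostics(
    model: FittedModel, design: DesignMatrix, config: AnalysisConfig
) -> DiagnosticsReport:
    resid = pearson_residuals(model, design)
    model_df = model.lag_order if config.ljung_box_adjust_df else 0
    q, p = ljung_box_test(resid, config.ljung_box_lags, model_df=model_df)
    k = len(model.coefficients) + 1
    ratio = float(np.sum(resid**2) / max(model.n_obs - k, 1))
    return DiagnosticsReport(q, p, config.ljung_box_lags, resid, ratio)


def ljung_box_test(
    residuals: np.ndarray, n_lags: int, model_df: int = 0
) -> tuple[float, float]:
    """Portmanteau test for residual autocorrelation up to lag ``n_lags``.

    Q = n(n+2) * sum_{k<=m} rho_k^2 / (n-k), referred to chi-square with
    m - model_df degrees of freedom (``model_df`` discounts fitted
    autoregressive parameters).
    """
    resid = np.asarray(residuals, dtype=float)
    if len(resid) <= n_lags:
        raise ValueError("residual series must be longer than n_lags")
    if np.ptp(resid) == 0:
        raise ValueError("autocorrelation undefined for a constant residual series")
    if model_df >= n_lags:
        raise ValueError("model_df must be smaller than n_lags")
    tbl = acorr_ljungbox(resid, lags=[n_lags], model_df=model_df)
    return float(tbl["lb_stat"].iloc[0]), float(tbl["lb_pvalue"].iloc[0])


def select_lag_order(
    series: DailySeries,
    calendar: EventCalendar,
    config: AnalysisConfig,
) -> LagSelection:
    """Forward stepwise choice of the autoregressive order by AIC.

    Starting from the no-lag model, lags 1..d are added one at a time and
    kept while the AIC improves; the returned order is the AIC-minimising
    contiguous set visited. Ljung-Box diagnostics of the selected model's
    Pearson residuals are recorded in the report.
    """
    if config.max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    aics: dict[int, float] = {}
    fits: dict[int, tuple[FittedModel, DesignMatrix]] = {}
    best_d = 0
    for d in range(0, config.max_lag + 1):
        dm = build_pretreatment_design(series, calendar, config, lag_order=d)
        fit = fit_nb(dm)
        aics[d] = fit.aic
        fits[d] = (fit, dm)
        if d > 0 and aics[d] >= aics[best_d]:
            break
        best_d = d
    model, dm = fits[best_d]
    report = diagnostics(model, dm, config)
    return LagSelection(best_d, aics, model, report)
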