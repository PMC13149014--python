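import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings
from scipy.special import gammaln

import itsim

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def nb2_loglik(y, mu, theta):
    """Hand-written NB2 log-likelihood, independent of the fitting code."""
    y = np.asarray(y, dtype=float)
    return float(
        np.sum(
            gammaln(y + theta)
            - gammaln(theta)
            - gammaln(y + 1)
            + theta * np.log(theta / (theta + mu))
            + y * np.log(mu / (theta + mu))
        )
    )


def make_series(counts, start="2015-01-01", population=10_000.0, label="events"):
    """Small hand-built DailySeries with a constant annual population."""
    counts = np.asarray(counts)
    idx = pd.date_range(start, periods=len(counts), freq="D")
    pop = np.full(len(counts), float(population))
    return itsim.DailySeries(
        pd.DataFrame({"count": counts, "population": pop}, index=idx), label
    )


@pytest.fixture(scope="session")
def mortality_params3():
    """Mortality-scale generator preset trimmed to 3 study years."""
    return itsim.default_params("mortality", n_years=3)


@pytest.fixture(scope="session")
def series3(mortality_params3):
    return itsim.generate_series(mortality_params3, seed=2021)


@pytest.fixture(scope="session")
def config_fast():
    return itsim.AnalysisConfig(seed=5, lag_order=1, n_sims=300)


@pytest.fixture(scope="session")
def result3(series3, mortality_params3, config_fast):
    return itsim.analyze(series3, mortality_params3.calendar, config_fast)
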