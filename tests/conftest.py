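import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from elshydro.cohort import CohortConfig, generate_cohort
from elshydro.features import add_predictors


@pytest.fixture(scope="session")
def cohort():
    """Default-size cohort (94 control ears + 86 uMD ears), fixed seed."""
    return generate_cohort(CohortConfig(seed=7))


@pytest.fixture(scope="session")
def predictors(cohort):
    return add_predictors(cohort)


@pytest.fixture(scope="session")
def small_cohort():
    """Down-sized cohort for refit-heavy tests."""
    return add_predictors(generate_cohort(CohortConfig(n_controls=15, n_patients=20, seed=3)))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def simulate_logistic(rng, n, beta0, beta1):
    """Bernoulli draws from a single-predictor logistic model."""
    x = rng.standard_normal(n)
    p = 1.0 / (1.0 + np.exp(-(beta0 + beta1 * x)))
    y = (rng.random(n) < p).astype(float)
    return pd.DataFrame({"x": x, "MD": y})
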