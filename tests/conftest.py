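import numpy as np
import pytest
from hypothesis import settings

from beetlecast.features import build_feature_matrix, cv_folds, year_based_split
from beetlecast.synthetic_data import (
    SimulationParams,
    default_survey,
    generate_landscape,
    generate_weather,
)

settings.register_profile("ci", deadline=None, max_examples=50, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def landscape():
    return generate_landscape(20, 20, seed=7)


@pytest.fixture(scope="session")
def weather(landscape):
    return generate_weather(landscape, list(range(2005, 2019)), seed=7)


@pytest.fixture(scope="session")
def survey():
    """Default-condition synthetic survey on a small park (13 survey years)."""
    return default_survey(12, 12, (2005, 2018), seed=11)


@pytest.fixture(scope="session")
def fm_r1h1(survey):
    return build_feature_matrix(survey, r=1, h=1)


@pytest.fixture(scope="session")
def train_setup(fm_r1h1):
    plan = year_based_split(fm_r1h1)
    folds = cv_folds(fm_r1h1, plan)
    return fm_r1h1, plan, folds


def logistic_sample(n, coefs, intercept, seed=0):
    """Data from a known logistic model, for parameter-recovery tests."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, len(coefs)))
    eta = intercept + X @ np.asarray(coefs)
    y = (rng.random(n) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
    return X, y
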