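import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import dsimmune as d

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return d.cohort.simulate_participants(d.CohortSpec(n_t21=40, n_d21=20, seed=11))


@pytest.fixture(scope="session")
def medium_cohort() -> pd.DataFrame:
    return d.cohort.simulate_participants(d.CohortSpec(n_t21=200, n_d21=100, seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
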