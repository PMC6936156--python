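import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from peis import PeisModel, simulate_cohort

settings.register_profile(
    "peis",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("peis")


@pytest.fixture(scope="session")
def small_cohort():
    """Light paired cohort exercising every stage quickly."""
    return simulate_cohort(
        n_patients=20, n_sites=3000, n_informative_hyper=150,
        n_informative_hypo=150, seed=11,
    )


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    c = small_cohort
    return PeisModel(c.beta, c.annotation, c.design, k=300).fit()


@pytest.fixture(scope="session")
def default_cohort():
    """The generator's default study conditions (30 patients, 20k sites,
    500 + 500 informative, kappa = 150, purities U(0.3, 0.9), seed 2019)."""
    return simulate_cohort()


@pytest.fixture(scope="session")
def default_fit(default_cohort):
    c = default_cohort
    return PeisModel(c.beta, c.annotation, c.design).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(424242)
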