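import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from tcore.ingest import aggregate_cohort
from tcore.simulate import SimConfig, simulate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")

#: known generating observation polynomials (coefficients in true Tc,
#: ascending degree) used by the known-coefficient generator mode
KNOWN_POLYS = {
    "hr": (1348.0, -108.0, 2.0),
    "skin_temp": (4.0, 0.8),
    "skin_rh": (-400.0, 12.0),
}


@pytest.fixture(scope="session")
def cohort_bio():
    """Small biophysical-mode cohort: streams from the two-node model."""
    return simulate_cohort(6, SimConfig(rng_seed=11))


@pytest.fixture(scope="session")
def frame_bio(cohort_bio):
    return aggregate_cohort(cohort_bio.trials)


@pytest.fixture(scope="session")
def profiles_bio(cohort_bio):
    return cohort_bio.profiles


@pytest.fixture(scope="session")
def cohort_known():
    """Cohort whose sensor channels are known polynomials of the true Tc."""
    return simulate_cohort(8, SimConfig(rng_seed=13, obs_polynomials=dict(KNOWN_POLYS)))


@pytest.fixture(scope="session")
def frame_known(cohort_known):
    return aggregate_cohort(cohort_known.trials)


@pytest.fixture(scope="session")
def profiles_known(cohort_known):
    return cohort_known.profiles
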