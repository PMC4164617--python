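import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dwiresponse import CohortConfig, PhantomConfig, generate_cohort, generate_phantom

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def small_phantom():
    """Small noiseless phantom: (study, voi, truth) with tumor ADC 0.75."""
    cfg = PhantomConfig(dims=(32, 28, 4), semi_axes=(6.0, 5.0, 1.4),
                        snr=float("inf"), seed=7)
    return generate_phantom(cfg)


@pytest.fixture
def study_cohort():
    """One synthetic 12-vs-11 cohort at the study's group parameters."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
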