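import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

from planets_pirates import TaskConfig
from planets_pirates.cohort import generate_cohort


@pytest.fixture(scope="session")
def default_config():
    return TaskConfig()


@pytest.fixture(scope="session")
def small_cohort():
    """A 24-agent cohort shared across analysis tests (30% sensitive)."""
    return generate_cohort(24, sensitive_fraction=0.3, seed=202)


@pytest.fixture(scope="session")
def cohort_frames(small_cohort):
    return {
        "events": small_cohort.events_frame(),
        "self_reports": small_cohort.self_reports_frame(),
        "questionnaires": small_cohort.questionnaires_frame(),
        "manifest": small_cohort.manifest,
    }


@pytest.fixture
def rng():
    return np.random.default_rng(0)
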