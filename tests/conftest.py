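import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from swipescreen.cohort import CohortConfig, generate_cohort

settings.register_profile(
    "swipescreen",
    deadline=None,
    max_examples=60,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("swipescreen")


def tiny_config(**overrides) -> CohortConfig:
    """A fast cohort config for unit tests: few participants, short sessions,
    sparse sensor sampling. Statistical acceptance checks use full defaults."""
    kwargs = dict(
        n_participants=5,
        seed=42,
        swipes_per_session={"puzzle": 25, "runner": 30, "slicer": 25},
        sensor_rate_hz=2.0,
    )
    kwargs.update(overrides)
    return CohortConfig(**kwargs)


@pytest.fixture(scope="session")
def tiny_cohort():
    """5-participant cohort across all 3 games (sessions, questionnaire table)."""
    return generate_cohort(tiny_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
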