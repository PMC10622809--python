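import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from dyadscan import synthgen as gen

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_timeline() -> gen.StimulusTimeline:
    """Reduced timeline: 3 localizer clips plus a 2-minute drama block."""
    return gen.build_timeline(n_localizers=3, drama_duration=120.0)


@pytest.fixture(scope="session")
def small_cohort(small_timeline) -> gen.Cohort:
    """Small default-condition cohort: 4 singles + 2 dyads."""
    config = gen.GeneratorConfig(n_single=4, n_dyads=2, seed=7)
    return gen.generate_cohort(config, small_timeline)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
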