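import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lfpclean import SynthSpec, make_fixture

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def small_fixture():
    """A 120-s seeded synthetic recording with injected artefacts, labelled,
    segmented and split -- shared by tests that only need a realistic
    pipeline state, not the full-scale study conditions."""
    return make_fixture(SynthSpec(duration_s=120.0, seed=7))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
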