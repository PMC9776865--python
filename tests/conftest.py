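import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from radiomut.synthetic import make_fixture_cohort

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def fixture_cohort():
    """The fixed-seed 47-patient synthetic cohort (features, labels)."""
    return make_fixture_cohort()


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
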