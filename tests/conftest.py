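import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def group_params():
    from parotid_dx.cohort_sim import default_group_params

    return default_group_params()


@pytest.fixture
def timing():
    from parotid_dx.cohort_sim import DceTiming

    return DceTiming()
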