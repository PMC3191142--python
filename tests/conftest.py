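import logging

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dmncausal as dc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

# the uncorrected-multiple-testing warning is intentional and noisy in tests
logging.getLogger("dmncausal.surrogate").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def control_spec():
    return dc.make_default_coupling("control")


@pytest.fixture(scope="session")
def control_subject(control_spec):
    """One simulated control subject at the study dimensions."""
    return dc.simulate_subject(control_spec, 295, seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def white_pair(rng):
    """Two independent Gaussian white-noise series at study length."""
    return rng.normal(size=295), rng.normal(size=295)
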