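import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(autouse=True)
def _quiet_substrate_depletion_warnings():
    # fast-reactivating simulated subjects legitimately trip the linearity guard
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*MPAG depleted.*")
        yield


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
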