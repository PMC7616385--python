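import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_params():
    """A small, fast parameter set used across simulator tests."""
    from sociowalk import SimParams

    return SimParams(N=20, rho0=0.5, k_h=1.0, k_L=1.0, T=2000, t_c=500, r=0.05)
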