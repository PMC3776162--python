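import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import tcell_calcium as tc

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def params():
    """Default parameter set, steady-state closure applied."""
    return tc.default_params()


@pytest.fixture(scope="session")
def fig3_trace(params):
    """Reference simulation: sustained TCR stimulation at 2 mM calcium."""
    proto = tc.preset("fig3", params)
    return tc.integrate(params, proto)


@pytest.fixture(scope="session")
def noiseless_target(params):
    """Synthetic fig3 target lying exactly on the model curve."""
    spec = tc.TargetSpec(params, protocol="fig3", noise_sd=0.0)
    return tc.generate_target(spec)


def pytest_configure(config):
    # warm the compiled integrator once so individual tests stay fast
    p = tc.default_params()
    proto = tc.preset("fig3", p)
    tc.integrate(p, proto, sample_times=np.array([1.0]))
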