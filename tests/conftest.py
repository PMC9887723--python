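import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import formadose as fd

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def params() -> fd.KineticParameters:
    return fd.KineticParameters()


@pytest.fixture(scope="session")
def steady(params) -> fd.MucosalState:
    return fd.endogenous_steady_state(params)


@pytest.fixture(scope="session")
def casanova_exogdpx(params, steady):
    """Predicted exogDPX at 1947 h of the chronic protocol, keyed by ppm.

    Shared across the dose-response worked examples and the superlinearity
    check so each chronic simulation runs once per session.
    """
    out = {}
    for ppm in (2.06, 6.01, 15.8):
        sched = fd.casanova_schedule(ppm)
        traj = fd.integrate(params, fd.DPX_SITE, sched, steady, [1947.0])
        out[ppm] = traj.value_at(1947.0, "exogDPX")
    return out


@pytest.fixture(scope="session")
def dose_response_curve(params):
    """Four-species dose-response over 0.7-15 ppm (chronic DPX protocol,
    repeated-daily DG protocol)."""
    grid = np.geomspace(0.7, 15.0, 9)
    return fd.dose_response(params, grid)
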