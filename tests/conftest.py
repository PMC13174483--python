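import numpy as np
import pytest

from thrombogen.coagulation import build_coagulation_model
from thrombogen.coupling import default_coupling_params
from thrombogen.inflammation import default_kinetics
from thrombogen.patients import normal_patient


@pytest.fixture(scope="session")
def coag_model():
    return build_coagulation_model()


@pytest.fixture(scope="session")
def kinetics():
    return default_kinetics()


@pytest.fixture(scope="session")
def coupling_params(kinetics):
    return default_coupling_params(kinetics)


@pytest.fixture(scope="session")
def reference_patient(kinetics):
    return normal_patient(kinetics)


def rk4_integrate(rhs, y0, t_end, dt):
    """Fixed-step classical Runge-Kutta oracle, independent of solve_ivp."""
    y = np.array(y0, float)
    t = 0.0
    n = int(round(t_end / dt))
    for _ in range(n):
        k1 = rhs(t, y)
        k2 = rhs(t + dt / 2, y + dt / 2 * k1)
        k3 = rhs(t + dt / 2, y + dt / 2 * k2)
        k4 = rhs(t + dt, y + dt * k3)
        y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
        t += dt
    return y
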