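import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pktopd import (
    MOUSE_ERROR,
    MOUSE_PD,
    MOUSE_PK,
    MOUSE_TO,
    fit_sequential,
)
from pktopd.model import ErrorModel
from pktopd.synth import StudyDesign, generate_study

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

TRUTH = {
    "clp": 5.14, "vp": 35.7,
    "kon": 0.0372, "koff": 0.113, "brmax": 0.987, "bltr": 21.6,
    "bl": 3.48, "kout": 1.32, "imax": 0.877,
}


def rk4_system(dose_mg_kg, t_end, dt=0.001, pk=MOUSE_PK, to=MOUSE_TO,
               pd=MOUSE_PD, scaled=True):
    """Independent fixed-step classic RK4 integration of the three-layer
    system after a bolus at t = 0.  Deliberately reimplements the
    right-hand side so it shares no code with the package integrators.
    """
    clp, vp = pk.clp, pk.vp
    kon, koff, brmax = to.kon, to.koff, to.brmax
    bl, kout, imax = pd.bl, pd.kout, pd.imax
    kin = bl * kout

    def f(y):
        ap, occ, ds = y
        cp = ap / vp
        inhib = imax * occ / brmax if scaled else imax * occ
        return np.array([
            -clp / vp * ap,
            kon * (brmax - occ) * cp - koff * occ,
            kin - kout * ds * (1.0 - inhib),
        ])

    n = int(round(t_end / dt))
    times = np.linspace(0.0, n * dt, n + 1)
    out = np.empty((n + 1, 3))
    y = np.array([1000.0 * dose_mg_kg, 0.0, bl])
    out[0] = y
    for _ in range(n):
        k1 = f(y)
        k2 = f(y + 0.5 * dt * k1)
        k3 = f(y + 0.5 * dt * k2)
        k4 = f(y + dt * k3)
        y = y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
        out[_ + 1] = y
    return times, out


@pytest.fixture(scope="session")
def clean_table():
    """Noise-free synthetic study at the default design and true params."""
    table, _ = generate_study(
        StudyDesign(seed=1), MOUSE_PK, MOUSE_TO, MOUSE_PD,
        ErrorModel(0.0, 0.0, 0.0),
    )
    return table


@pytest.fixture(scope="session")
def noisy_table():
    """One synthetic study at the study's residual-error magnitudes."""
    table, _ = generate_study(
        StudyDesign(seed=7), MOUSE_PK, MOUSE_TO, MOUSE_PD, MOUSE_ERROR,
    )
    return table


@pytest.fixture(scope="session")
def clean_fit(clean_table):
    return fit_sequential(clean_table, n_starts=2, seed=0)
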