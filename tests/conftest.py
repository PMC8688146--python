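import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fdgkin.kinetic_model import FrameSchedule
from fdgkin.plasma import FengInput


@pytest.fixture(scope="session")
def schedule() -> FrameSchedule:
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def feng() -> FengInput:
    return FengInput()


def ode_tissue_curve(params, plasma, times, rtol=1e-10):
    """Independent oracle: direct stiff integration of the compartment ODEs."""

    def rhs(t, y):
        cf, cb = y
        return [
            params.k1 * float(plasma(t)) - (params.k2 + params.k3) * cf + params.k4 * cb,
            params.k3 * cf - params.k4 * cb,
        ]

    sol = solve_ivp(
        rhs, (0.0, times[-1]), [0.0, 0.0], t_eval=times,
        rtol=rtol, atol=1e-13, method="LSODA",
    )
    return sol.y.sum(axis=0)
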