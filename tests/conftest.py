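import dataclasses

import numpy as np
import pytest

from ifsigtt.cohort import DEFAULT_SAMPLE_TIMES, ProtocolSpec, SubjectSeries
from ifsigtt.synth import FOAL_PRESET, HORSE_PRESET


def make_series(times, glucose, insulin, subject_id="s1", group="foal", age=None):
    return SubjectSeries(
        subject_id=subject_id, group=group,
        times=np.asarray(times, dtype=float),
        glucose=np.asarray(glucose, dtype=float),
        insulin=np.asarray(insulin, dtype=float),
        age=age,
    )


@pytest.fixture
def protocol():
    return ProtocolSpec()


@pytest.fixture
def protocol_times():
    return np.asarray(DEFAULT_SAMPLE_TIMES, dtype=float)


def noise_free(preset):
    """Preset copy with all between-subject and measurement noise removed."""
    return dataclasses.replace(
        preset, between_subject_cv=0.0, measurement_cv=0.0,
        measurement_cv_insulin=0.0,
    )


@pytest.fixture
def foal_noise_free():
    return noise_free(FOAL_PRESET)


@pytest.fixture
def horse_noise_free():
    return noise_free(HORSE_PRESET)


def rk4_minimal_model(params, forcing, t_grid, h=1e-3):
    """Independent fixed-step RK4 integration of the raw two-ODE system.

    Deliberately naive: integrates dG/dt and dX/dt directly with a classical
    Runge-Kutta step, no closed forms shared with the implementation.
    """
    sg, p2, p3 = params.sg, params.p2, params.p3
    gb, ib = params.gb, params.ib

    def rhs(t, y):
        g, x = y
        i = float(forcing(t))
        return np.array([-(sg + x) * g + sg * gb, -p2 * x + p3 * (i - ib)])

    out = [params.g0]
    y = np.array([params.g0, 0.0])
    t = float(t_grid[0])
    for tk in np.asarray(t_grid, dtype=float)[1:]:
        n = max(1, int(round((tk - t) / h)))
        hh = (tk - t) / n
        for _ in range(n):
            k1 = rhs(t, y)
            k2 = rhs(t + hh / 2, y + hh / 2 * k1)
            k3 = rhs(t + hh / 2, y + hh / 2 * k2)
            k4 = rhs(t + hh, y + hh * k3)
            y = y + hh / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            t += hh
        t = float(tk)
        out.append(y[0])
    return np.array(out)
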