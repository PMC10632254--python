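"""Shared fixtures: synthetic beats, cohorts and velocity fields."""

import numpy as np
import pytest

from wavesep import Waveform
from wavesep.synthetic import SimulationGroundTruth, simulate_beat, simulate_cohort

CYCLE_MS = 60000.0 / 70.0
T_SYS_MS = 300.0


def smooth_flow_beat(n=128, cycle=CYCLE_MS, tsys=T_SYS_MS, amplitude=1.0):
    """A C^2-smooth unit ejection bump: (4 x (1 - x))^2.5 over systole.

    Smooth enough that Savitzky-Golay smoothing at the default span leaves
    a residual below 1e-3, which the generator's half-sine (with its
    derivative kink at the peak) does not.
    """
    t = np.arange(n) * (cycle / n)
    x = np.clip(t / tsys, 0.0, 1.0)
    v = amplitude * (4.0 * x * (1.0 - x)) ** 2.5
    v[(t < 0) | (t > tsys)] = 0.0
    return Waveform(t, v, "flow", cycle)


def smooth_tube_beat(gamma=0.4, delay=120.0, zc=0.1, baseline=80.0, amp=40.0,
                     n=128, cycle=CYCLE_MS, tsys=T_SYS_MS):
    """Tube-load pressure/flow pair driven by the smooth ejection bump."""
    t = np.arange(n) * (cycle / n)

    def F(tt):
        x = np.clip(tt / tsys, 0.0, 1.0)
        out = amp * (4.0 * x * (1.0 - x)) ** 2.5
        out[(tt < 0) | (tt > tsys)] = 0.0
        return out

    pf, pb = F(t), gamma * F(t - delay)
    p = Waveform(t, pf + pb + baseline, "pressure", cycle)
    q = Waveform(t, (pf - pb) / zc, "flow", cycle)
    return p, q


@pytest.fixture(scope="session")
def gt_default():
    return SimulationGroundTruth()


@pytest.fixture(scope="session")
def beat(gt_default):
    """Default noiseless tube-load beat: (pressure, flow, area)."""
    return simulate_beat(gt_default)


@pytest.fixture(scope="session")
def cohort20():
    """20-subject jittered cohort at the default ranges, fixed seed."""
    return simulate_cohort(SimulationGroundTruth(), 20, seed=20260925)
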