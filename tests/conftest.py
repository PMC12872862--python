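import numpy as np
import pytest

from pvloops.core import CuffPressure, ValveEvents
from pvloops.pv_analysis import PVLoop
from pvloops.reference_waveform import build_default_reference
from pvloops.simulator import SimParams, simulate_beat, simulate_cohort


@pytest.fixture(scope="session")
def reference():
    return build_default_reference()


@pytest.fixture
def events():
    return ValveEvents(0.02, 0.09, 0.38, 0.47, 0.9)


@pytest.fixture
def cuff_as():
    """Severe-AS cuff pressures (cohort baseline means)."""
    return CuffPressure(159.0, 73.0)


@pytest.fixture
def rect_loop():
    """Rectangular PV loop: V 140<->60 mL, P 10<->110 mmHg, counter-clockwise.

    Closed-form metrics: SW = 8000, ESP = 110 at V_es = 60, EDV = 140.
    """
    v = np.array([140.0, 140.0, 60.0, 60.0])
    p = np.array([10.0, 110.0, 110.0, 10.0])
    t = np.array([0.0, 0.25, 0.5, 0.75])
    return PVLoop(volume=v, pressure=p, time=t)


@pytest.fixture(scope="session")
def default_beat():
    return simulate_beat(SimParams())


@pytest.fixture(scope="session")
def cohort50():
    return simulate_cohort(50, seed=1)
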