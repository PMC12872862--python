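"""Pressure-strain myocardial work: segmental components and global indices."""

import numpy as np
import pytest

from pvloops.core import AlignmentError, PressureTrace, StrainTraceSet, ValveEvents
from pvloops.myocardial_work import global_mwi, segment_work


def _ease(s):
    return 0.5 - 0.5 * np.cos(np.pi * s)


@pytest.fixture
def mwi_events():
    return ValveEvents(0.0, 0.07, 0.40, 0.50, 0.9)


@pytest.fixture
def grid():
    return np.arange(180) / 200.0


def _systolic_shortening(t, events, amplitude=-20.0, ivr_delta=0.0):
    """Smooth strain: 0 -> amplitude over systole, optional IVR excursion."""
    eps = np.zeros_like(t)
    sys_mask = t <= events.t_avc
    eps[sys_mask] = amplitude * _ease(t[sys_mask] / events.t_avc)
    eps[~sys_mask] = amplitude
    ivr_mask = (t > events.t_avc) & (t <= events.t_mvo)
    if ivr_delta:
        eps[ivr_mask] += ivr_delta * _ease(
            (t[ivr_mask] - events.t_avc) / events.ivr_time
        )
        eps[t > events.t_mvo] += ivr_delta
    return eps


class TestSegmentWork:
    def test_constant_strain_zero_work(self, grid, mwi_events):
        p = PressureTrace(time=grid, pressure=np.full_like(grid, 100.0))
        w = segment_work(p, np.zeros_like(grid), mwi_events)
        assert w == {"constructive": 0.0, "wasted": 0.0, "net": 0.0}

    def test_pure_systolic_shortening(self, grid, mwi_events):
        """P = 100 mmHg, strain 0 -> -20% during systole, flat in IVR:
        constructive work is the rectangle 100 mmHg x 20% = 2000 mmHg%."""
        p = PressureTrace(time=grid, pressure=np.full_like(grid, 100.0))
        eps = _systolic_shortening(grid, mwi_events, amplitude=-20.0)
        w = segment_work(p, eps, mwi_events)
        assert w["constructive"] == pytest.approx(2000.0, rel=1e-3)
        assert w["wasted"] == pytest.approx(0.0, abs=1.0)
        assert w["net"] == pytest.approx(2000.0, rel=1e-3)

    def test_systolic_lengthening_is_wasted(self, grid, mwi_events):
        p = PressureTrace(time=grid, pressure=np.full_like(grid, 100.0))
        eps = _systolic_shortening(grid, mwi_events, amplitude=+10.0)
        w = segment_work(p, eps, mwi_events)
        assert w["constructive"] == pytest.approx(0.0, abs=1.0)
        assert w["wasted"] == pytest.approx(1000.0, rel=1e-3)

    def test_ivr_lengthening_is_constructive(self, grid, mwi_events):
        p = PressureTrace(time=grid, pressure=np.full_like(grid, 100.0))
        eps = _systolic_shortening(grid, mwi_events, amplitude=-20.0, ivr_delta=+5.0)
        w = segment_work(p, eps, mwi_events)
        assert w["constructive"] == pytest.approx(2500.0, rel=1e-2)

    def test_off_grid_strain_rejected(self, grid, mwi_events):
        p = PressureTrace(time=grid, pressure=np.full_like(grid, 100.0))
        with pytest.raises(AlignmentError):
            segment_work(p, np.zeros(50), mwi_events)


class TestGlobalMWI:
    def _strain_set(self, grid, mwi_events, n=18, phase_shift_half=False):
        rows = []
        for i in range(n):
            if phase_shift_half and i >= n // 2:
                # delayed activation: lengthens early systole, shortens in IVR
                eps = np.interp(grid - 0.08, grid, _systolic_shortening(grid, mwi_events))
            else:
                eps = _systolic_shortening(grid, mwi_events)
            rows.append(eps)
        return StrainTraceSet(time=grid, strain=np.array(rows))

    def test_identical_segments_equal_single(self, grid, mwi_events):
        p = PressureTrace(time=grid, pressure=np.full_like(grid, 100.0))
        strains = self._strain_set(grid, mwi_events)
        single = segment_work(p, strains.strain[0], mwi_events)
        m = global_mwi(p, strains, mwi_events)
        assert m.gwi == pytest.approx(single["net"])
        assert m.gcw == pytest.approx(single["constructive"])
        assert m.gwe == pytest.approx(100.0, abs=0.1)
        assert len(m.per_segment) == 18

    def test_synchronous_shortening_full_efficiency(self, grid, mwi_events):
        p = PressureTrace(time=grid, pressure=np.full_like(grid, 100.0))
        m = global_mwi(p, self._strain_set(grid, mwi_events), mwi_events)
        assert m.gww == pytest.approx(0.0, abs=1.0)
        assert m.gwe == pytest.approx(100.0, abs=0.1)

    def test_dyssynchrony_reduces_efficiency(self, grid, mwi_events):
        p = PressureTrace(time=grid, pressure=np.full_like(grid, 100.0))
        m_sync = global_mwi(p, self._strain_set(grid, mwi_events), mwi_events)
        m_dys = global_mwi(
            p, self._strain_set(grid, mwi_events, phase_shift_half=True), mwi_events
        )
        assert m_dys.gww > m_sync.gww
        assert m_dys.gwe < 99.0
        assert 0 <= m_dys.gwe <= 100

    def test_pressure_doubling_scales_work_not_efficiency(self, grid, mwi_events):
        strains = self._strain_set(grid, mwi_events, phase_shift_half=True)
        p1 = PressureTrace(time=grid, pressure=np.full_like(grid, 100.0))
        p2 = PressureTrace(time=grid, pressure=np.full_like(grid, 200.0))
        m1, m2 = global_mwi(p1, strains, mwi_events), global_mwi(p2, strains, mwi_events)
        assert m2.gwi == pytest.approx(2 * m1.gwi, rel=1e-9)
        assert m2.gcw == pytest.approx(2 * m1.gcw, rel=1e-9)
        assert m2.gww == pytest.approx(2 * m1.gww, rel=1e-9)
        assert m2.gwe == pytest.approx(m1.gwe, rel=1e-9)

    def test_grid_refinement_invariance(self, mwi_events):
        """GWI changes by <0.5% when the shared grid is refined 4x."""
        vals = []
        for rate in (200, 800):
            t = np.arange(int(0.9 * rate)) / rate
            p = PressureTrace(time=t, pressure=80 + 60 * np.sin(np.pi * t / 0.9))
            eps = _systolic_shortening(t, mwi_events)
            strains = StrainTraceSet(time=t, strain=eps[None, :])
            vals.append(global_mwi(p, strains, mwi_events).gwi)
        assert vals[1] == pytest.approx(vals[0], rel=5e-3)

    def test_segment_order_invariance(self, grid, mwi_events):
        p = PressureTrace(time=grid, pressure=np.full_like(grid, 100.0))
        s = self._strain_set(grid, mwi_events, phase_shift_half=True)
        shuffled = StrainTraceSet(time=grid, strain=s.strain[::-1].copy())
        assert global_mwi(p, shuffled, mwi_events).gwi == pytest.approx(
            global_mwi(p, s, mwi_events).gwi
        )
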