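"""Individualized LV pressure waveform estimation from cuff pressure,
transvalvular gradient, and valvular event timing.

The method rests on a generic normalized LV pressure template that is warped
horizontally so its phase landmarks coincide with the patient's measured
valve events (mitral closure MVC, aortic opening AVO, aortic closure AVC,
mitral opening MVO), and scaled vertically by a single affine map anchored at
two points:

* peak LV pressure = brachial systolic cuff pressure + mean transaortic
  gradient (the gradient term is zero without outflow obstruction), and
* LV pressure at aortic valve opening = diastolic cuff pressure.

The original multi-patient averaged template is not distributed; this module
ships a documented parametric template with the same landmark structure, and
accepts a user-supplied reference curve from CSV so that a site-specific
averaged curve can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .core import (
    CuffPressure,
    DegenerateInputError,
    PressureTrace,
    ValveEvents,
)

__all__ = [
    "ReferenceCurve",
    "EstimatedPressure",
    "build_default_reference",
    "load_reference_curve",
    "save_reference_curve",
    "estimate_pressure",
]

#: Normalized pressure the default template assigns at aortic valve opening.
DEFAULT_P_AVO = 0.45


@dataclass(frozen=True)
class ReferenceCurve:
    """Normalized generic LV pressure template over one cycle.

    ``phase`` is a uniform grid on [0, 1] with MVC at phase 0 and cycle end at
    phase 1; ``p_norm`` is normalized pressure with maximum exactly 1 attained
    once, between the AVO and AVC landmarks.  ``landmarks`` holds the
    normalized phases of ``avo``, ``avc``, ``mvo`` and ``peak`` (``mvc`` is 0
    by convention).
    """

    phase: np.ndarray
    p_norm: np.ndarray
    landmarks: dict

    def __post_init__(self) -> None:
        object.__setattr__(self, "phase", np.asarray(self.phase, dtype=float))
        object.__setattr__(self, "p_norm", np.asarray(self.p_norm, dtype=float))
        if self.phase.shape != self.p_norm.shape or self.phase.ndim != 1:
            raise ValueError("phase and p_norm must be equal-length 1-D arrays")
        if self.phase[0] != 0.0 or self.phase[-1] != 1.0:
            raise ValueError("phase grid must span [0, 1]")
        lm = self.landmarks
        order = (0.0, lm["avo"], lm["avc"], lm["mvo"], 1.0)
        if not all(a < b for a, b in zip(order, order[1:])):
            raise ValueError(f"landmarks must satisfy 0 < AVO < AVC < MVO < 1, got {lm}")
        if np.any(self.p_norm < 0):
            raise ValueError("p_norm must be non-negative")
        peaks = np.flatnonzero(self.p_norm == self.p_norm.max())
        if self.p_norm.max() != 1.0 or peaks.size != 1:
            raise ValueError("p_norm must attain its maximum 1 exactly once")
        ppos = self.phase[peaks[0]]
        if not (lm["avo"] < ppos < lm["avc"]):
            raise ValueError("template peak must lie between AVO and AVC")

    @property
    def peak_phase(self) -> float:
        return float(self.landmarks["peak"])

    def p_at(self, phase) -> np.ndarray:
        return np.interp(phase, self.phase, self.p_norm)


def _ease(s: np.ndarray) -> np.ndarray:
    """Raised-cosine smoothstep on [0, 1] with zero slope at both ends."""
    return 0.5 - 0.5 * np.cos(np.pi * s)


def build_default_reference(
    n_samples: int = 500,
    *,
    avo: float = 0.10,
    avc: float = 0.42,
    mvo: float = 0.52,
    peak_within_ejection: float = 0.45,
    p_avo: float = DEFAULT_P_AVO,
    p_avc: float = 0.80,
    p_diastolic_min: float = 0.06,
    p_end_diastolic: float = 0.12,
) -> ReferenceCurve:
    """Construct the package's parametric normalized LV pressure template.

    The systolic limb is a raised cosine rising from ``p_avo`` at aortic valve
    opening to 1 at the peak (placed ``peak_within_ejection`` of the way
    through ejection) and falling to ``p_avc`` at aortic valve closure; the
    diastolic limb decays to a low plateau and drifts gently up to the
    end-diastolic level.  All segment joins are C1 (zero-slope cosine easing),
    so the maximum 1 is attained exactly once.

    Landmark phases are snapped to the nearest grid point so that they are
    exact interpolation knots of downstream warping.
    """
    if n_samples < 100:
        raise ValueError(f"n_samples must be >= 100, got {n_samples}")
    if not (0 < avo < avc < mvo < 1):
        raise ValueError("require 0 < avo < avc < mvo < 1")
    if not (0 < peak_within_ejection < 1):
        raise ValueError("peak_within_ejection must be in (0, 1)")
    if not (0 < p_diastolic_min <= p_end_diastolic < p_avo < 1 and 0 < p_avc < 1):
        raise ValueError("template pressure levels out of order")

    phase = np.linspace(0.0, 1.0, n_samples)

    def snap(x: float) -> float:
        return float(phase[int(round(x * (n_samples - 1)))])

    avo, avc, mvo = snap(avo), snap(avc), snap(mvo)
    peak = snap(avo + peak_within_ejection * (avc - avo))

    p = np.empty_like(phase)
    segments = [
        (0.0, avo, p_end_diastolic, p_avo),   # isovolumic contraction
        (avo, peak, p_avo, 1.0),              # early ejection
        (peak, avc, 1.0, p_avc),              # late ejection
        (avc, mvo, p_avc, p_diastolic_min),   # isovolumic relaxation
        (mvo, 1.0, p_diastolic_min, p_end_diastolic),  # filling
    ]
    for t0, t1, y0, y1 in segments:
        m = (phase >= t0) & (phase <= t1)
        s = (phase[m] - t0) / (t1 - t0)
        p[m] = y0 + (y1 - y0) * _ease(s)

    landmarks = {"mvc": 0.0, "avo": avo, "avc": avc, "mvo": mvo, "peak": peak}
    return ReferenceCurve(phase=phase, p_norm=p, landmarks=landmarks)


def save_reference_curve(curve: ReferenceCurve, path) -> None:
    """Write a reference curve as CSV with a landmark header comment."""
    lm = curve.landmarks
    header = (
        f"# landmarks: avo={lm['avo']:.17g},avc={lm['avc']:.17g},"
        f"mvo={lm['mvo']:.17g},peak={lm['peak']:.17g}\n"
        "phase,p_norm\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        for ph, pn in zip(curve.phase, curve.p_norm):
            fh.write(f"{ph:.17g},{pn:.17g}\n")


def load_reference_curve(path) -> ReferenceCurve:
    """Read a reference curve CSV (columns ``phase,p_norm``) whose first line
    is a comment declaring the landmark phases, e.g.
    ``# landmarks: avo=0.1,avc=0.42,mvo=0.52,peak=0.244``.
    """
    with open(path) as fh:
        first = fh.readline().strip()
    if not first.startswith("#") or "landmarks:" not in first:
        raise ValueError(
            f"{path}: first line must be a '# landmarks: ...' comment"
        )
    lm_part = first.split("landmarks:", 1)[1]
    landmarks = {"mvc": 0.0}
    for item in lm_part.split(","):
        key, _, val = item.partition("=")
        landmarks[key.strip()] = float(val)
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    return ReferenceCurve(
        phase=df["phase"].to_numpy(float),
        p_norm=df["p_norm"].to_numpy(float),
        landmarks=landmarks,
    )


@dataclass
class EstimatedPressure(PressureTrace):
    """Uniformly sampled estimated LV pressure plus its continuous curve.

    ``curve_at`` evaluates the underlying monotone piecewise-cubic model,
    for which the anchoring contract holds exactly: ``curve_at(peak_time)``
    equals systolic cuff pressure + mean gradient and ``curve_at(t_avo)``
    equals the diastolic cuff pressure.
    """

    peak_pressure: float = 0.0
    peak_time: float = 0.0
    events: ValveEvents | None = None
    _curve: PchipInterpolator | None = field(default=None, repr=False, compare=False)
    _floor: float = 0.0

    def curve_at(self, t) -> np.ndarray:
        """Evaluate the continuous estimated pressure at time(s) ``t``,
        periodic over the cycle."""
        if self._curve is None or self.events is None:
            return self.value_at(t)
        t = np.asarray(t, dtype=float)
        t0 = self.events.t_mvc
        cl = self.events.cycle_length
        tt = t0 + np.mod(t - t0, cl)
        return np.maximum(self._curve(tt), self._floor)


def estimate_pressure(
    ref: ReferenceCurve,
    events: ValveEvents,
    cuff: CuffPressure,
    mean_gradient: float = 0.0,
    *,
    sample_rate_hz: float = 200.0,
    pressure_floor: float = 2.0,
) -> EstimatedPressure:
    """Scale the reference template into an individualized LV pressure trace.

    Horizontal scaling is the strictly increasing piecewise-linear time warp
    mapping the template landmark phases (MVC, AVO, AVC, MVO, cycle end) onto
    the measured event times; the template peak is thereby placed
    proportionally within the AVO-AVC segment.  Vertical scaling is the affine
    map ``a*p_norm + b`` solving ``a*1 + b = SBP + gradient`` and
    ``a*p_norm(AVO) + b = DBP``.  Diastolic values are clamped at
    ``pressure_floor`` (the template makes no fidelity claim in diastole).

    Returns the trace resampled on a uniform grid over ``[0, cycle_length)``.
    """
    if mean_gradient < 0:
        raise ValueError(f"mean_gradient must be >= 0, got {mean_gradient}")
    peak_target = cuff.systolic + mean_gradient
    p_avo = float(ref.p_at(ref.landmarks["avo"]))
    a = (peak_target - cuff.diastolic) / (1.0 - p_avo)
    b = peak_target - a
    if a <= 0:
        raise DegenerateInputError(
            "vertical scale is non-positive: peak target "
            f"{peak_target} mmHg does not exceed diastolic {cuff.diastolic} mmHg"
        )
    if peak_target <= pressure_floor:
        raise DegenerateInputError("scaled systolic pressure is not positive")

    lm = ref.landmarks
    x = np.array([0.0, lm["avo"], lm["avc"], lm["mvo"], 1.0])
    y = np.array(
        [
            events.t_mvc,
            events.t_avo,
            events.t_avc,
            events.t_mvo,
            events.t_mvc + events.cycle_length,
        ]
    )
    t_warp = np.interp(ref.phase, x, y)
    p_warp = np.maximum(a * ref.p_norm + b, pressure_floor)
    # strictly increasing by construction (warp is a piecewise-linear bijection)
    curve = PchipInterpolator(t_warp, p_warp)

    n = int(round(events.cycle_length * sample_rate_hz))
    if n < 50:
        raise ValueError(
            f"sample_rate_hz {sample_rate_hz} yields only {n} samples per cycle"
        )
    t = np.arange(n) / sample_rate_hz
    tt = np.where(t >= events.t_mvc, t, t + events.cycle_length)
    p = np.maximum(curve(tt), pressure_floor)

    peak_time = float(np.interp(lm["peak"], x, y))
    return EstimatedPressure(
        time=t,
        pressure=p,
        peak_pressure=peak_target,
        peak_time=peak_time,
        events=events,
        _curve=curve,
        _floor=pressure_floor,
    )
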