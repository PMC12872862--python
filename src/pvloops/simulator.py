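"""Synthetic paired ground-truth LV pressure/volume beats.

The simulator is kinematic: the volume waveform is prescribed (smooth cosine
ejection and filling limbs around isovolumic plateaus) and LV pressure
follows from a time-varying elastance model,

    P(t) = E(t) * (V(t) - V0),

with E(t) a double-Hill curve rising to its maximum at aortic valve closure
(maximal elastance at end-ejection) and decaying during relaxation.  Aortic
stenosis is modelled as an instantaneous transvalvular gradient proportional
to the square of transvalvular flow, ``dP = k * Q**2`` with ``Q = -dV/dt``
during ejection; aortic pressure is LV pressure minus the gradient.  The
"cuff" systolic pressure is the peak aortic pressure and the diastolic cuff
pressure is the aortic (= LV, since flow is zero) pressure at aortic valve
opening, matching the operating assumption that brachial pressures proxy
central aortic extremes.

Because the ejection flow is an analytic half-sine, the mean transvalvular
gradient has the closed form ``k * (SV*pi/(2*Te))**2 / 2`` (Te = ejection
time), which is also used to choose ``k`` for a target gradient.

The default beat emulates a severe-aortic-stenosis patient with preserved
ejection fraction: EDV 172 mL, SV 93 mL, heart rate 67/min, mean gradient
51 mmHg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .core import CuffPressure, DegenerateInputError, PressureTrace, ValveEvents, VolumeTrace
from .pv_analysis import PVMetrics, build_loop, compute_metrics

__all__ = [
    "SimParams",
    "SimBeat",
    "simulate_beat",
    "simulate_cohort",
    "stenosis_coefficient_for_gradient",
    "double_hill",
    "elastance",
    "DEFAULT_COHORT_RANGES",
]

#: Default target mean transvalvular gradient for the default beat, mmHg.
DEFAULT_MEAN_GRADIENT = 51.0


def double_hill(
    s, *, n1: float = 1.3, n2: float = 21.9, a1: float = 1.0, a2: float = 0.508
) -> np.ndarray:
    """Unnormalized double-Hill activation: a fast rising Hill term times a
    steep decaying one.  ``s`` is dimensionless time."""
    s = np.asarray(s, dtype=float)
    rise = (s / a1) ** n1
    return (rise / (1.0 + rise)) / (1.0 + (s / a2) ** n2)


def _double_hill_peak(n1: float, n2: float, a1: float, a2: float) -> tuple[float, float]:
    """Location and value of the double-Hill maximum (dense grid + refinement)."""
    s = np.linspace(1e-6, 1.5, 20001)
    g = double_hill(s, n1=n1, n2=n2, a1=a1, a2=a2)
    i = int(np.argmax(g))
    lo, hi = s[max(i - 1, 0)], s[min(i + 1, s.size - 1)]
    fine = np.linspace(lo, hi, 2001)
    gf = double_hill(fine, n1=n1, n2=n2, a1=a1, a2=a2)
    j = int(np.argmax(gf))
    return float(fine[j]), float(gf[j])


def elastance(
    t,
    *,
    t_peak: float,
    e_min: float,
    e_max: float,
    n1: float = 1.3,
    n2: float = 21.9,
    a1: float = 1.0,
    a2: float = 0.508,
) -> np.ndarray:
    """Time-varying elastance E(t) in mmHg/mL, maximal (= ``e_max``) at
    ``t_peak`` and decaying towards ``e_min`` in diastole."""
    s_peak, g_peak = _double_hill_peak(n1, n2, a1, a2)
    s = np.asarray(t, dtype=float) * (s_peak / t_peak)
    g = double_hill(s, n1=n1, n2=n2, a1=a1, a2=a2) / g_peak
    return e_min + (e_max - e_min) * g


def stenosis_coefficient_for_gradient(
    mean_gradient: float, sv: float, ejection_time: float
) -> float:
    """Stenosis coefficient k (mmHg*s^2/mL^2) that yields the requested mean
    transvalvular gradient for a half-sine ejection flow profile."""
    if mean_gradient < 0:
        raise ValueError("mean_gradient must be >= 0")
    q_peak = sv * math.pi / (2.0 * ejection_time)
    return 2.0 * mean_gradient / q_peak**2


@dataclass(frozen=True)
class SimParams:
    """Ground-truth beat parameters.

    Timing fractions place the valve events within the cycle (MVC at t = 0);
    ejection spans ``avo_frac`` to ``avc_frac`` of the cycle and filling spans
    ``mvo_frac`` to cycle end.  ``stenosis_coefficient`` defaults to the value
    giving a mean transvalvular gradient of 51 mmHg for this beat; set it to 0
    for no outflow obstruction.
    """

    edv: float = 172.0
    sv: float = 93.0
    e_max: float = 2.7
    e_min: float = 0.08
    v0: float = 10.0
    cycle_length: float = 0.9
    avo_frac: float = 0.07
    avc_frac: float = 0.40
    mvo_frac: float = 0.50
    stenosis_coefficient: float | None = None
    sample_rate_hz: float = 200.0
    hill_n1: float = 1.3
    hill_n2: float = 21.9
    hill_a1: float = 1.0
    hill_a2: float = 0.508

    def __post_init__(self) -> None:
        if not (self.edv > self.sv > 0):
            raise ValueError("require EDV > SV > 0")
        if not (self.e_max > self.e_min > 0):
            raise ValueError("require E_max > E_min > 0")
        if self.edv - self.sv <= self.v0:
            raise ValueError("end-systolic volume must exceed V0")
        if not (0 < self.avo_frac < self.avc_frac < self.mvo_frac < 1):
            raise ValueError("timing fractions must satisfy 0 < AVO < AVC < MVO < 1")
        if self.stenosis_coefficient is None:
            k = stenosis_coefficient_for_gradient(
                DEFAULT_MEAN_GRADIENT, self.sv, self.ejection_time
            )
            object.__setattr__(self, "stenosis_coefficient", k)
        if self.stenosis_coefficient < 0:
            raise ValueError("stenosis_coefficient must be >= 0")

    @property
    def ejection_time(self) -> float:
        return (self.avc_frac - self.avo_frac) * self.cycle_length

    @property
    def events(self) -> ValveEvents:
        cl = self.cycle_length
        return ValveEvents(0.0, self.avo_frac * cl, self.avc_frac * cl, self.mvo_frac * cl, cl)


@dataclass
class SimBeat:
    """One simulated beat: ground truth plus the non-invasive inputs."""

    true_pressure: PressureTrace
    volume: VolumeTrace
    cuff: CuffPressure
    mean_gradient: float
    events: ValveEvents
    true_metrics: PVMetrics
    t_emax: float  # time of maximal elastance (end-systolic oracle)
    params: SimParams = field(repr=False, default=None)


def _ease(s: np.ndarray) -> np.ndarray:
    return 0.5 - 0.5 * np.cos(np.pi * s)


def simulate_beat(params: SimParams) -> SimBeat:
    """Generate one ground-truth beat from the elastance model."""
    cl = params.cycle_length
    ev = params.events
    n = int(round(cl * params.sample_rate_hz))
    t = np.arange(n) / params.sample_rate_hz

    te = params.ejection_time
    esv = params.edv - params.sv
    vol = np.full(n, params.edv)
    ej = (t >= ev.t_avo) & (t <= ev.t_avc)
    vol[ej] = params.edv - params.sv * _ease((t[ej] - ev.t_avo) / te)
    iso = (t > ev.t_avc) & (t < ev.t_mvo)
    vol[iso] = esv
    fill = t >= ev.t_mvo
    vol[fill] = esv + params.sv * _ease((t[fill] - ev.t_mvo) / (cl - ev.t_mvo))

    e_kw = dict(
        t_peak=ev.t_avc,
        e_min=params.e_min,
        e_max=params.e_max,
        n1=params.hill_n1,
        n2=params.hill_n2,
        a1=params.hill_a1,
        a2=params.hill_a2,
    )
    lvp = elastance(t, **e_kw) * (vol - params.v0)
    if np.min(lvp) <= 0:
        raise DegenerateInputError(
            "parameter combination yields non-positive LV pressure "
            f"(min {np.min(lvp):.2f} mmHg)"
        )

    k = params.stenosis_coefficient
    q = np.zeros(n)
    q[ej] = params.sv * (np.pi / (2.0 * te)) * np.sin(np.pi * (t[ej] - ev.t_avo) / te)
    grad = k * q**2
    pao_ej = lvp[ej] - grad[ej]
    if np.min(pao_ej) <= 0:
        raise DegenerateInputError("stenosis gradient drives aortic pressure negative")
    cuff_sys = float(np.max(pao_ej))
    # flow is zero at valve opening, so aortic = LV pressure there (analytic)
    e_avo = float(elastance(np.array([ev.t_avo]), **e_kw)[0])
    cuff_dia = e_avo * (params.edv - params.v0)
    if cuff_sys <= cuff_dia:
        raise DegenerateInputError(
            "stenosis gradient depresses systolic aortic pressure below the "
            "diastolic level"
        )
    mean_gradient = k * (params.sv * np.pi / (2.0 * te)) ** 2 / 2.0

    ptrace = PressureTrace(time=t, pressure=lvp)
    vtrace = VolumeTrace(time=t, volume=vol)
    loop = build_loop(ptrace, vtrace)
    metrics = compute_metrics(loop)
    return SimBeat(
        true_pressure=ptrace,
        volume=vtrace,
        cuff=CuffPressure(systolic=cuff_sys, diastolic=cuff_dia),
        mean_gradient=float(mean_gradient),
        events=ev,
        true_metrics=metrics,
        t_emax=ev.t_avc,
        params=params,
    )


#: Parameter ranges emulating a severe-AS cohort with preserved EF.
DEFAULT_COHORT_RANGES: dict = {
    "edv": (140.0, 210.0),
    "ef": (0.45, 0.62),
    "e_max": (2.0, 3.4),
    "e_min": (0.05, 0.12),
    "v0": (0.0, 15.0),
    "cycle_length": (0.7, 1.1),
    "mean_gradient": (30.0, 80.0),
}


def simulate_cohort(
    n: int,
    seed: int,
    param_ranges: dict | None = None,
    *,
    base_params: SimParams | None = None,
) -> list[SimBeat]:
    """Simulate ``n`` beats with parameters drawn uniformly from
    ``param_ranges`` (defaults: :data:`DEFAULT_COHORT_RANGES`), reproducibly
    for a fixed ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    ranges = dict(DEFAULT_COHORT_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    base = base_params or SimParams()
    rng = np.random.default_rng(seed)
    beats: list[SimBeat] = []
    attempts = 0
    max_attempts = 100 * n
    while len(beats) < n:
        if attempts >= max_attempts:
            raise DegenerateInputError(
                f"could not draw {n} physiologically admissible beats in "
                f"{max_attempts} attempts; narrow the parameter ranges"
            )
        attempts += 1
        draw = {key: float(rng.uniform(*bounds)) for key, bounds in ranges.items()}
        sv = draw["ef"] * draw["edv"]
        te = (base.avc_frac - base.avo_frac) * draw["cycle_length"]
        k = stenosis_coefficient_for_gradient(draw["mean_gradient"], sv, te)
        params = replace(
            base,
            edv=draw["edv"],
            sv=sv,
            e_max=draw["e_max"],
            e_min=draw["e_min"],
            v0=draw["v0"],
            cycle_length=draw["cycle_length"],
            stenosis_coefficient=k,
        )
        try:
            beats.append(simulate_beat(params))
        except (DegenerateInputError, ValueError):
            # a gradient/contractility combination the circulation could not
            # sustain; redraw (deterministic under the seed)
            continue
    return beats


def noninvasive_metrics(beat: SimBeat, ref=None) -> PVMetrics:
    """Run the full non-invasive pipeline on a simulated beat: estimate the
    pressure waveform from cuff + gradient + events, pair it with the beat's
    volume trace, and compute loop metrics."""
    from .reference_waveform import build_default_reference, estimate_pressure

    if ref is None:
        ref = build_default_reference()
    est = estimate_pressure(
        ref,
        beat.events,
        beat.cuff,
        beat.mean_gradient,
        sample_rate_hz=beat.params.sample_rate_hz if beat.params else 200.0,
    )
    loop = build_loop(est, beat.volume)
    return compute_metrics(loop)
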