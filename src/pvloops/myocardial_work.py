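"""Pressure-strain myocardial work index (GWI, GCW, GWW, GWE).

Segmental work is the time integral of instantaneous myocardial power,
``P(t) * (-d(strain)/dt)`` (pressure in mmHg, strain in percent, so work has
units mmHg%), taken from mitral valve closure to mitral valve opening.  The
constructive/wasted partition distinguishes the mechanical effect of
shortening versus lengthening by cardiac phase:

* systole (MVC -> AVC): shortening performs constructive work, systolic
  lengthening (stretch) is wasted work;
* isovolumic relaxation (AVC -> MVO): lengthening is constructive (it aids
  relaxation), post-systolic shortening is wasted.

Global indices average the segmental values: GWI is the mean net work
(constructive - wasted), GCW/GWW the mean components, and work efficiency
GWE = 100 * GCW / (GCW + GWW).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import AlignmentError, PressureTrace, StrainTraceSet, ValveEvents

__all__ = ["MWIMetrics", "segment_work", "global_mwi"]


@dataclass(frozen=True)
class MWIMetrics:
    """Global myocardial work indices (mmHg% except GWE, %) with the
    per-segment work table."""

    gwi: float
    gcw: float
    gww: float
    gwe: float
    per_segment: pd.DataFrame

    def to_dict(self) -> dict:
        return {"gwi": self.gwi, "gcw": self.gcw, "gww": self.gww, "gwe": self.gwe}

    def to_json(self, path=None) -> str:
        d = self.to_dict()
        d["per_segment"] = self.per_segment.to_dict(orient="list")
        s = json.dumps(d, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def _interval_integral(power: np.ndarray, time: np.ndarray, mask: np.ndarray) -> tuple:
    """Trapezoid integrals of the positive and negative parts of ``power``
    over the masked (contiguous) interval."""
    if mask.sum() < 2:
        return 0.0, 0.0
    t = time[mask]
    w = power[mask]
    pos = float(np.trapezoid(np.maximum(w, 0.0), t))
    neg = float(np.trapezoid(np.maximum(-w, 0.0), t))
    return pos, neg


def segment_work(
    p: PressureTrace,
    strain: np.ndarray,
    events: ValveEvents,
) -> dict:
    """Work components for one segmental strain trace (percent) on the
    pressure trace's grid.

    Returns a dict with ``constructive``, ``wasted`` and ``net`` work in
    mmHg%.
    """
    strain = np.asarray(strain, dtype=float)
    if strain.shape != p.time.shape:
        raise AlignmentError(
            f"strain trace has {strain.size} samples but the pressure grid has "
            f"{p.time.size}; resample onto the shared grid first"
        )
    dstrain = np.gradient(strain, p.time)  # centered differences, %/s
    power = p.pressure * (-dstrain)  # positive while shortening

    t = p.time
    systole = (t >= events.t_mvc) & (t <= events.t_avc)
    ivr = (t >= events.t_avc) & (t <= events.t_mvo)

    short_sys, length_sys = _interval_integral(power, t, systole)
    short_ivr, length_ivr = _interval_integral(power, t, ivr)

    constructive = short_sys + length_ivr
    wasted = length_sys + short_ivr
    return {
        "constructive": constructive,
        "wasted": wasted,
        "net": constructive - wasted,
    }


def global_mwi(
    p: PressureTrace,
    strains: StrainTraceSet,
    events: ValveEvents,
) -> MWIMetrics:
    """Global myocardial work indices from all segmental strain traces."""
    if strains.n_segments < 1:
        raise ValueError("need at least one strain segment")
    if strains.time.shape != p.time.shape or not np.allclose(strains.time, p.time):
        raise AlignmentError(
            "strain set is not on the pressure grid; resample onto the shared grid"
        )
    rows = []
    for sid, tr in zip(strains.segment_ids, strains.strain):
        w = segment_work(p, tr, events)
        rows.append({"segment": sid, **w})
    table = pd.DataFrame(rows)
    gcw = float(table["constructive"].mean())
    gww = float(table["wasted"].mean())
    gwi = float(table["net"].mean())
    denom = gcw + gww
    gwe = 100.0 * gcw / denom if denom > 0 else 100.0
    return MWIMetrics(gwi=gwi, gcw=gcw, gww=gww, gwe=gwe, per_segment=table)
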