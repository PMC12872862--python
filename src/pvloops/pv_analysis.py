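"""Pressure-volume loop construction and loop-derived energetic metrics.

The loop is the closed polygon traced by paired (volume, pressure) samples
over one cardiac cycle.  Derived quantities:

* stroke work SW: area enclosed by the loop (shoelace formula), mmHg*mL;
* end-systolic point: the vertex in the upper-left region of the loop with
  the greatest normalized distance from the loop's geometric center;
* end-systolic elastance Ees: slope of the line from the end-systolic point
  to the volume axis at the fixed intercept V0 = 0 mL (single-beat
  convention; with V0 = 0 this is a lower bound on the true-V0 slope);
* arterial elastance Ea = ESP / SV; ventriculo-arterial coupling VAC =
  Ea / Ees;
* potential energy PE = 0.5 * ESP * (V_es - V0): the triangle under the
  ESPVR down to V0, with the end-diastolic pressure-volume relationship
  taken as zero (the diastolic limb is deliberately not modelled);
* pressure-volume area PVA = SW + PE and ventricular efficiency
  100 * SW / PVA;
* single-beat contractility ratios ESP/EDV and Pmax/EDV.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .core import DegenerateInputError, DetectionError, PressureTrace, VolumeTrace

__all__ = [
    "PVLoop",
    "PVMetrics",
    "build_loop",
    "loop_area",
    "end_systolic_point",
    "compute_metrics",
    "signed_loop_area",
]


@dataclass
class PVLoop:
    """Closed pressure-volume polygon (implicit closure last -> first vertex).

    After :func:`build_loop` the traversal is normalized to counter-clockwise
    in the (volume, pressure) plane.  ``time`` (optional) keeps the original
    acquisition times of the vertices for timing queries and tie-breaking.
    """

    volume: np.ndarray
    pressure: np.ndarray
    time: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        self.pressure = np.asarray(self.pressure, dtype=float)
        if self.volume.shape != self.pressure.shape or self.volume.ndim != 1:
            raise ValueError("volume and pressure must be equal-length 1-D arrays")
        if self.volume.size < 4:
            raise ValueError("a loop needs at least 4 vertices")
        if self.time is not None:
            self.time = np.asarray(self.time, dtype=float)
            if self.time.shape != self.volume.shape:
                raise ValueError("time must match vertex count")

    @property
    def n_vertices(self) -> int:
        return self.volume.size


def signed_loop_area(volume: np.ndarray, pressure: np.ndarray) -> float:
    """Signed shoelace area of the implicitly closed (V, P) polygon;
    positive for counter-clockwise traversal."""
    v = np.asarray(volume, dtype=float)
    p = np.asarray(pressure, dtype=float)
    return 0.5 * float(np.sum(v * np.roll(p, -1) - np.roll(v, -1) * p))


def build_loop(
    p: PressureTrace,
    v: VolumeTrace,
    *,
    min_vertices: int = 50,
) -> PVLoop:
    """Pair synchronized pressure and volume traces into a closed PV loop.

    The traces must share an identical uniform grid (see
    :func:`pvloops.trace_io.synchronize`).  Traversal orientation is
    normalized to counter-clockwise; a loop with (numerically) zero enclosed
    area is rejected.
    """
    if p.time.shape != v.time.shape or not np.allclose(p.time, v.time):
        raise ValueError("traces must share an identical time grid; synchronize first")
    if not v.is_uniform:
        raise ValueError("traces must be uniformly sampled")
    vol, press, t = v.volume, p.pressure, v.time
    # drop a duplicated closing vertex if the cycle was stored inclusively
    if vol.size > 4 and vol[0] == vol[-1] and press[0] == press[-1]:
        vol, press, t = vol[:-1], press[:-1], t[:-1]
    if vol.size < min_vertices:
        raise ValueError(f"loop has {vol.size} vertices, need >= {min_vertices}")
    area = signed_loop_area(vol, press)
    scale = np.ptp(vol) * np.ptp(press)
    if scale <= 0 or abs(area) <= 1e-9 * max(scale, 1.0):
        raise DegenerateInputError("pressure-volume loop encloses no area")
    if area < 0:
        vol, press, t = vol[::-1], press[::-1], t[::-1]
    return PVLoop(volume=vol, pressure=press, time=t)


def loop_area(loop: PVLoop) -> float:
    """Enclosed loop area (stroke work), mmHg*mL — absolute shoelace area."""
    return abs(signed_loop_area(loop.volume, loop.pressure))


def end_systolic_point(loop: PVLoop) -> int:
    """Index of the end-systolic vertex.

    Volume and pressure are each min-max normalized to [0, 1]; the geometric
    center is the vertex mean of the normalized coordinates.  Among vertices
    strictly left of and above the center (lower volume, higher pressure),
    the one with the greatest Euclidean distance from the center is returned;
    exact ties are broken by earliest acquisition time.
    """
    v, p = loop.volume, loop.pressure
    vr, pr = np.ptp(v), np.ptp(p)
    if vr <= 0 or pr <= 0:
        raise DetectionError("degenerate loop: no volume or pressure excursion")
    vhat = (v - v.min()) / vr
    phat = (p - p.min()) / pr
    cv, cp = vhat.mean(), phat.mean()
    candidates = np.flatnonzero((vhat < cv) & (phat > cp))
    if candidates.size == 0:
        raise DetectionError("no vertex lies in the upper-left region of the loop")
    d2 = (vhat[candidates] - cv) ** 2 + (phat[candidates] - cp) ** 2
    best = candidates[np.abs(d2 - d2.max()) <= 1e-12 * max(d2.max(), 1.0)]
    if best.size > 1 and loop.time is not None:
        return int(best[np.argmin(loop.time[best])])
    return int(best[0])


@dataclass(frozen=True)
class PVMetrics:
    """Scalar metrics derived from one pressure-volume loop.

    Units: SW/PE/PVA mmHg*mL; Ees/Ea/ESP_over_EDV/Pmax_over_EDV mmHg/mL;
    VAC dimensionless; efficiency %; ESP mmHg; volumes mL.
    """

    sw: float
    pe: float
    pva: float
    ees: float
    ea: float
    vac: float
    efficiency: float
    esp: float
    v_es: float
    edv: float
    esv: float
    sv: float
    esp_over_edv: float
    pmax_over_edv: float
    v0: float = 0.0

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    def to_csv_row(self, path=None) -> str:
        d = self.to_dict()
        units = {
            "sw": "mmHg*mL", "pe": "mmHg*mL", "pva": "mmHg*mL",
            "ees": "mmHg/mL", "ea": "mmHg/mL", "vac": "-", "efficiency": "%",
            "esp": "mmHg", "v_es": "mL", "edv": "mL", "esv": "mL", "sv": "mL",
            "esp_over_edv": "mmHg/mL", "pmax_over_edv": "mmHg/mL", "v0": "mL",
        }
        header = ",".join(f"{k} [{units[k]}]" for k in d)
        row = ",".join(f"{val:.6g}" for val in d.values())
        s = header + "\n" + row + "\n"
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s


def compute_metrics(loop: PVLoop, *, v0: float = 0.0) -> PVMetrics:
    """Compute the full metric set from a PV loop.

    ``v0`` is the (arbitrary) ESPVR volume-axis intercept; the single-beat
    convention fixes it at 0 mL.  End-systolic volume for Ees and PE is the
    volume at the detected end-systolic vertex; ESV for stroke volume is the
    cycle's minimum volume.
    """
    sw = loop_area(loop)
    i_es = end_systolic_point(loop)
    esp = float(loop.pressure[i_es])
    v_es = float(loop.volume[i_es])
    edv = float(np.max(loop.volume))
    esv = float(np.min(loop.volume))
    sv = edv - esv
    if sv <= 0:
        raise DegenerateInputError("stroke volume is not positive")
    if esp <= 0:
        raise DegenerateInputError("end-systolic pressure is not positive")
    if v_es <= v0:
        raise DegenerateInputError(
            f"end-systolic volume {v_es} mL does not exceed V0 = {v0} mL"
        )
    ees = esp / (v_es - v0)
    ea = esp / sv
    vac = ea / ees
    pe = 0.5 * esp * (v_es - v0)
    pva = sw + pe
    efficiency = 100.0 * sw / pva
    pmax = float(np.max(loop.pressure))
    return PVMetrics(
        sw=sw,
        pe=pe,
        pva=pva,
        ees=ees,
        ea=ea,
        vac=vac,
        efficiency=efficiency,
        esp=esp,
        v_es=v_es,
        edv=edv,
        esv=esv,
        sv=sv,
        esp_over_edv=esp / edv,
        pmax_over_edv=pmax / edv,
        v0=v0,
    )
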