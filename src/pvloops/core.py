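"""Shared domain types for non-invasive pressure-volume analysis.

Physiological signals are represented as plain dataclasses holding NumPy
arrays over a single cardiac cycle.  The cycle convention throughout the
package is that ``t = 0`` corresponds to the R-wave (onset of systole) and a
trace spans exactly one cycle; closing the pressure-volume loop joins the
last sample back to the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CuffPressure",
    "ValveEvents",
    "PressureTrace",
    "VolumeTrace",
    "StrainTraceSet",
    "TraceParseError",
    "AlignmentError",
    "DegenerateInputError",
    "DetectionError",
]


class TraceParseError(ValueError):
    """A trace file failed validation (non-monotone time, NaN, too short)."""


class AlignmentError(ValueError):
    """Two traces cannot be placed on a shared cycle time base."""


class DegenerateInputError(ValueError):
    """Physiologically or geometrically degenerate input (zero-area loop,
    affine scaling that would force negative systolic pressures, ...)."""


class DetectionError(ValueError):
    """A landmark-detection step found no admissible candidate."""


def _asarray1d(x, name: str) -> np.ndarray:
    a = np.asarray(x, dtype=float)
    if a.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {a.shape}")
    if np.any(~np.isfinite(a)):
        raise ValueError(f"{name} contains non-finite values")
    return a


def _check_time(time: np.ndarray) -> None:
    if time.size < 2:
        raise ValueError("trace needs at least 2 samples")
    if np.any(np.diff(time) <= 0):
        raise ValueError("time must be strictly increasing")


@dataclass(frozen=True)
class CuffPressure:
    """Brachial cuff blood pressure (sphygmomanometer), mmHg."""

    systolic: float
    diastolic: float

    def __post_init__(self) -> None:
        if not (self.systolic > self.diastolic > 0):
            raise ValueError(
                f"require systolic > diastolic > 0, got "
                f"{self.systolic}/{self.diastolic} mmHg"
            )

    @property
    def pulse_pressure(self) -> float:
        return self.systolic - self.diastolic


@dataclass(frozen=True)
class ValveEvents:
    """Valvular event times within one cardiac cycle, seconds from the R-wave.

    MVC and AVO bracket isovolumic contraction, AVO and AVC bracket ejection,
    AVC and MVO bracket isovolumic relaxation, and MVO to cycle end is the
    filling phase.
    """

    t_mvc: float
    t_avo: float
    t_avc: float
    t_mvo: float
    cycle_length: float

    def __post_init__(self) -> None:
        seq = (self.t_mvc, self.t_avo, self.t_avc, self.t_mvo, self.cycle_length)
        if not (0 <= seq[0] < seq[1] < seq[2] < seq[3] < seq[4]):
            raise ValueError(
                "valve events must satisfy 0 <= MVC < AVO < AVC < MVO < cycle "
                f"length, got {seq}"
            )

    @property
    def ejection_time(self) -> float:
        return self.t_avc - self.t_avo

    @property
    def ivr_time(self) -> float:
        """Isovolumic relaxation time (AVC to MVO)."""
        return self.t_mvo - self.t_avc

    def as_dict(self) -> dict:
        return {
            "mvc": self.t_mvc,
            "avo": self.t_avo,
            "avc": self.t_avc,
            "mvo": self.t_mvo,
            "cycle_length": self.cycle_length,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ValveEvents":
        return cls(d["mvc"], d["avo"], d["avc"], d["mvo"], d["cycle_length"])


def _is_uniform(time: np.ndarray) -> bool:
    dt = np.diff(time)
    return bool(np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9))


@dataclass
class PressureTrace:
    """LV pressure over one cardiac cycle (mmHg on a time grid in seconds)."""

    time: np.ndarray
    pressure: np.ndarray

    def __post_init__(self) -> None:
        self.time = _asarray1d(self.time, "time")
        self.pressure = _asarray1d(self.pressure, "pressure")
        _check_time(self.time)
        if self.pressure.shape != self.time.shape:
            raise ValueError("time and pressure must have equal length")
        if np.any(self.pressure < 0):
            raise ValueError("pressure must be non-negative")

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def span(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def is_uniform(self) -> bool:
        return _is_uniform(self.time)

    def value_at(self, t) -> np.ndarray:
        """Linear interpolation of the sampled trace."""
        return np.interp(t, self.time, self.pressure)


@dataclass
class VolumeTrace:
    """LV cavity volume over one cardiac cycle (mL on a time grid in seconds)."""

    time: np.ndarray
    volume: np.ndarray

    def __post_init__(self) -> None:
        self.time = _asarray1d(self.time, "time")
        self.volume = _asarray1d(self.volume, "volume")
        _check_time(self.time)
        if self.volume.shape != self.time.shape:
            raise ValueError("time and volume must have equal length")
        if np.any(self.volume <= 0):
            raise ValueError("volume must be strictly positive")
        if np.ptp(self.volume) <= 0:
            raise ValueError("volume trace must not be constant")

    @property
    def n(self) -> int:
        return self.time.size

    @property
    def span(self) -> float:
        return float(self.time[-1] - self.time[0])

    @property
    def is_uniform(self) -> bool:
        return _is_uniform(self.time)

    @property
    def edv(self) -> float:
        """End-diastolic volume: the chamber's maximum volume."""
        return float(np.max(self.volume))

    @property
    def esv(self) -> float:
        """End-systolic volume: the chamber's minimum volume."""
        return float(np.min(self.volume))

    def value_at(self, t) -> np.ndarray:
        return np.interp(t, self.time, self.volume)


@dataclass
class StrainTraceSet:
    """Segmental longitudinal strain traces (%) sharing one time grid.

    Strain is referenced to cycle start: every segment's trace is rebased so
    that strain(0) = 0.
    """

    time: np.ndarray
    strain: np.ndarray  # (n_segments, n_samples), percent
    segment_ids: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.time = _asarray1d(self.time, "time")
        _check_time(self.time)
        self.strain = np.atleast_2d(np.asarray(self.strain, dtype=float))
        if np.any(~np.isfinite(self.strain)):
            raise ValueError("strain contains non-finite values")
        if self.strain.shape[1] != self.time.size:
            raise ValueError(
                f"strain has {self.strain.shape[1]} samples per segment but the "
                f"time grid has {self.time.size}"
            )
        if not self.segment_ids:
            self.segment_ids = [f"seg{i + 1:02d}" for i in range(self.n_segments)]
        if len(self.segment_ids) != self.strain.shape[0]:
            raise ValueError("segment_ids length must match number of segments")
        # reference at cycle start
        self.strain = self.strain - self.strain[:, :1]

    @property
    def n_segments(self) -> int:
        return self.strain.shape[0]

    @property
    def is_uniform(self) -> bool:
        return _is_uniform(self.time)
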