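"""Reading, validation, resampling and synchronization of cycle traces.

CSV dialects (comma-separated, dot decimal, header required):

* volume:   ``time_s,volume_ml``
* pressure: ``time_s,pressure_mmhg``
* strain:   ``time_s,seg01,...,segNN``  (percent)

Lines starting with ``#`` are ignored.  All downstream analysis modules
expect uniform, equal-length traces on a shared grid; :func:`synchronize`
produces exactly that.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .core import (
    AlignmentError,
    PressureTrace,
    StrainTraceSet,
    TraceParseError,
    VolumeTrace,
)

__all__ = [
    "read_trace",
    "write_trace",
    "resample",
    "synchronize",
    "VolumeTrace",
    "PressureTrace",
    "StrainTraceSet",
    "DEFAULT_RATE_HZ",
]

DEFAULT_RATE_HZ = 200.0
#: Maximum relative cycle-length mismatch tolerated by :func:`synchronize`.
DEFAULT_CYCLE_TOLERANCE = 0.05


def read_trace(path, kind: str):
    """Read and validate a trace CSV.

    Parameters
    ----------
    path : str or Path
        CSV file in one of the module's dialects.
    kind : {"volume", "pressure", "strain"}

    Returns
    -------
    VolumeTrace | PressureTrace | StrainTraceSet

    Raises
    ------
    TraceParseError
        On NaN values, non-monotone time (reported with the offending data
        row index), or fewer than 10 samples.
    """
    if kind not in ("volume", "pressure", "strain"):
        raise ValueError(f"unknown trace kind {kind!r}")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise TraceParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise TraceParseError(f"{path}: need at least two columns")
    if kind != "strain" and df.shape[1] != 2:
        raise TraceParseError(
            f"{path}: {kind} trace must have exactly two columns, got {df.shape[1]}"
        )
    if df.shape[0] < 10:
        raise TraceParseError(f"{path}: need at least 10 samples, got {df.shape[0]}")
    bad = df.isna().any(axis=1)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise TraceParseError(f"{path}: non-numeric or missing value at data row {row}")

    time = df.iloc[:, 0].to_numpy(dtype=float)
    dt = np.diff(time)
    if np.any(dt <= 0):
        row = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise TraceParseError(
            f"{path}: time not strictly increasing at data row {row} "
            f"(t={time[row]!r})"
        )

    if kind == "volume":
        return VolumeTrace(time=time, volume=df.iloc[:, 1].to_numpy(dtype=float))
    if kind == "pressure":
        return PressureTrace(time=time, pressure=df.iloc[:, 1].to_numpy(dtype=float))
    return StrainTraceSet(
        time=time,
        strain=df.iloc[:, 1:].to_numpy(dtype=float).T,
        segment_ids=list(df.columns[1:]),
    )


def write_trace(trace, path) -> None:
    """Write a trace in the matching CSV dialect."""
    if isinstance(trace, VolumeTrace):
        df = pd.DataFrame({"time_s": trace.time, "volume_ml": trace.volume})
    elif isinstance(trace, PressureTrace):
        df = pd.DataFrame({"time_s": trace.time, "pressure_mmhg": trace.pressure})
    elif isinstance(trace, StrainTraceSet):
        df = pd.DataFrame({"time_s": trace.time})
        for sid, row in zip(trace.segment_ids, trace.strain):
            df[sid] = row
    else:
        raise TypeError(f"cannot write object of type {type(trace)!r}")
    df.to_csv(path, index=False)


def _uniform_grid(t0: float, t1: float, rate_hz: float) -> np.ndarray:
    n = max(2, int(round((t1 - t0) * rate_hz)) + 1)
    return np.linspace(t0, t1, n)


def resample(trace, rate_hz: float):
    """Resample a trace onto a uniform grid spanning the same cycle.

    Monotone piecewise-cubic (PCHIP) interpolation: endpoint values are
    preserved exactly, linear input stays linear, and no overshoot beyond
    adjacent samples is introduced.  The returned grid has the closest
    uniform spacing to ``1/rate_hz`` that divides the span, so resampling is
    idempotent at a fixed rate.
    """
    if rate_hz <= 0:
        raise ValueError(f"rate_hz must be positive, got {rate_hz}")
    if isinstance(trace, VolumeTrace):
        t, y = trace.time, trace.volume
    elif isinstance(trace, PressureTrace):
        t, y = trace.time, trace.pressure
    elif isinstance(trace, StrainTraceSet):
        t, y = trace.time, trace.strain
    else:
        raise TypeError(f"cannot resample object of type {type(trace)!r}")
    grid = _uniform_grid(float(t[0]), float(t[-1]), rate_hz)
    interp = PchipInterpolator(t, y, axis=-1)
    ynew = interp(grid)
    if isinstance(trace, VolumeTrace):
        return VolumeTrace(time=grid, volume=ynew)
    if isinstance(trace, PressureTrace):
        return PressureTrace(time=grid, pressure=np.maximum(ynew, 0.0))
    return StrainTraceSet(time=grid, strain=ynew, segment_ids=list(trace.segment_ids))


def synchronize(
    p: PressureTrace,
    v: VolumeTrace,
    *,
    tolerance: float = DEFAULT_CYCLE_TOLERANCE,
    rate_hz: float = DEFAULT_RATE_HZ,
):
    """Place a pressure and a volume trace on one shared uniform grid.

    If the two cycle lengths differ by no more than ``tolerance`` (relative to
    the volume cycle), the pressure time axis is linearly rescaled to the
    volume cycle length — the volume trace defines the cycle because loop
    volumes (EDV, ESV, SV) are read from it directly.  Both traces are then
    resampled onto a uniform grid at ``rate_hz``.

    Raises
    ------
    AlignmentError
        If the cycle lengths differ by more than ``tolerance``.
    """
    lp, lv = p.span, v.span
    if abs(lp - lv) / lv > tolerance:
        raise AlignmentError(
            f"cycle-length mismatch beyond tolerance: pressure {lp:.4f} s vs "
            f"volume {lv:.4f} s ({abs(lp - lv) / lv:.1%} > {tolerance:.1%})"
        )
    if p.time.shape == v.time.shape and np.array_equal(p.time, v.time) and p.is_uniform:
        return p, v
    pt = v.time[0] + (p.time - p.time[0]) * (lv / lp)
    p_scaled = PressureTrace(time=pt, pressure=p.pressure)
    grid = _uniform_grid(float(v.time[0]), float(v.time[-1]), rate_hz)
    p_out = PressureTrace(
        time=grid,
        pressure=np.maximum(PchipInterpolator(pt, p_scaled.pressure)(grid), 0.0),
    )
    v_out = VolumeTrace(
        time=grid, volume=PchipInterpolator(v.time, v.volume)(grid)
    )
    return p_out, v_out
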