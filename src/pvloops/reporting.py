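"""Energetics bookkeeping and visit-change reporting.

The arithmetic identities relating the energetic quantities — pressure-volume
area as the sum of stroke work and potential energy, ventricular efficiency
as the percentage of PVA delivered as stroke work — live here so that both
the CLI reports and summary-level analyses go through the same code path.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "pressure_volume_area",
    "ventricular_efficiency",
    "visit_change_summary",
    "load_cohort_summary",
    "PV_METRIC_NAMES",
]

#: Canonical row names for the pressure-volume section of a visit report.
PV_METRIC_NAMES = [
    "stroke_work",
    "end_systolic_elastance",
    "arterial_elastance",
    "ventricular_efficiency",
    "esp_over_edv",
    "pmax_over_edv",
    "ventriculo_arterial_coupling",
    "pressure_volume_area",
    "potential_energy",
]

#: Mapping from PVMetrics field names to report row names.
METRIC_FIELD_TO_ROW = {
    "sw": "stroke_work",
    "ees": "end_systolic_elastance",
    "ea": "arterial_elastance",
    "efficiency": "ventricular_efficiency",
    "esp_over_edv": "esp_over_edv",
    "pmax_over_edv": "pmax_over_edv",
    "vac": "ventriculo_arterial_coupling",
    "pva": "pressure_volume_area",
    "pe": "potential_energy",
}


def pressure_volume_area(sw: float, pe: float) -> float:
    """PVA = SW + PE (mmHg*mL)."""
    return sw + pe


def ventricular_efficiency(sw: float, pva: float) -> float:
    """Efficiency = 100 * SW / PVA (%)."""
    if pva <= 0:
        raise ValueError("PVA must be positive")
    return 100.0 * sw / pva


def _complete(values: dict) -> dict:
    """Derive PVA and efficiency from SW and PE when absent."""
    out = dict(values)
    if "stroke_work" in out and "potential_energy" in out:
        out.setdefault(
            "pressure_volume_area",
            pressure_volume_area(out["stroke_work"], out["potential_energy"]),
        )
        out.setdefault(
            "ventricular_efficiency",
            ventricular_efficiency(out["stroke_work"], out["pressure_volume_area"]),
        )
    return out


def visit_change_summary(baseline: dict, followup: dict) -> pd.DataFrame:
    """Per-metric change between two visits.

    ``baseline`` and ``followup`` map metric row names to values (single
    patient or cohort means).  PVA and efficiency are derived from SW and PE
    through the same identities used on individual loops when not supplied.
    Returns a frame with columns ``metric, baseline, followup, change,
    relative_change_pct``.
    """
    b = _complete(baseline)
    f = _complete(followup)
    rows = []
    for name in sorted(set(b) & set(f), key=lambda s: (s not in PV_METRIC_NAMES, s)):
        change = f[name] - b[name]
        rel = 100.0 * change / b[name] if b[name] != 0 else float("nan")
        rows.append(
            {
                "metric": name,
                "baseline": b[name],
                "followup": f[name],
                "change": change,
                "relative_change_pct": rel,
            }
        )
    return pd.DataFrame(rows)


def load_cohort_summary() -> pd.DataFrame:
    """Bundled severe-AS TAVR cohort summary statistics (mean, SD per visit),
    indexed by metric name."""
    with resources.files("pvloops.data").joinpath("cohort_summary.csv").open() as fh:
        df = pd.read_csv(fh, comment="#")
    return df.set_index("metric")
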