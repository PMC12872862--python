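"""Method-comparison and observer-variability statistics.

Implements the comparison battery used for validating paired measurement
methods: Pearson correlation, ordinary least-squares regression, single-rater
intraclass correlation coefficients from ANOVA mean squares (one-way random
ICC(1,1), two-way random ICC(2,1), two-way mixed consistency ICC(3,1)), and
Bland-Altman bias with limits of agreement (bias +/- 1.96 * SD by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AgreementReport",
    "ICCResult",
    "icc",
    "bland_altman",
    "ols_fit",
    "paired_compare",
    "compare_methods",
    "agreement_report_frame",
    "LOA_MULTIPLIER",
]

#: Limits-of-agreement multiplier (normal 95% central interval).
LOA_MULTIPLIER = 1.96

ICC_MODELS = ("oneway_random", "twoway_random", "twoway_mixed_consistency")


@dataclass(frozen=True)
class ICCResult:
    value: float
    model: str
    warning: str | None = None


@dataclass(frozen=True)
class AgreementReport:
    """Agreement of two paired measurement vectors (a = test, b = reference)."""

    pearson_r: float
    icc: float
    icc_model: str
    ols_slope: float
    ols_intercept: float
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "icc": self.icc,
            "icc_model": self.icc_model,
            "ols_slope": self.ols_slope,
            "ols_intercept": self.ols_intercept,
            "bias": self.bias,
            "sd_diff": self.sd_diff,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
            "n": self.n,
        }


def _paired(a, b, min_n: int) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size != b.size:
        raise ValueError(f"paired vectors differ in length: {a.size} vs {b.size}")
    if a.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {a.size}")
    return a, b


def icc(x_pairs, model: str = "twoway_mixed_consistency") -> ICCResult:
    """Single-rater intraclass correlation from ANOVA mean squares.

    ``x_pairs`` is an (n_subjects, k_raters) table.  Models:

    * ``oneway_random``: ICC(1,1) — each subject rated by a different random
      set of raters (intraobserver designs);
    * ``twoway_random``: ICC(2,1) — absolute agreement, raters a random sample
      (interobserver designs);
    * ``twoway_mixed_consistency``: ICC(3,1) — consistency, raters fixed; a
      constant offset between raters does not reduce it.

    Zero between-subject variance yields a defined (<= 0) value flagged with a
    warning instead of an error.
    """
    if model not in ICC_MODELS:
        raise ValueError(f"model must be one of {ICC_MODELS}, got {model!r}")
    x = np.asarray(x_pairs, dtype=float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 2:
        raise ValueError(
            f"need an (n >= 3 subjects, k >= 2 raters) table, got shape {x.shape}"
        )
    n, k = x.shape
    grand = x.mean()
    subj = x.mean(axis=1)
    rater = x.mean(axis=0)

    ss_total = float(((x - grand) ** 2).sum())
    ss_subject = float(k * ((subj - grand) ** 2).sum())
    ss_rater = float(n * ((rater - grand) ** 2).sum())
    ss_within = ss_total - ss_subject
    ss_error = ss_total - ss_subject - ss_rater

    msb = ss_subject / (n - 1)
    msw = ss_within / (n * (k - 1))
    msc = ss_rater / (k - 1)
    mse = ss_error / ((n - 1) * (k - 1))

    if model == "oneway_random":
        value = (msb - msw) / (msb + (k - 1) * msw)
    elif model == "twoway_random":
        value = (msb - mse) / (msb + (k - 1) * mse + k * (msc - mse) / n)
    else:
        value = (msb - mse) / (msb + (k - 1) * mse)

    warning = None
    if ss_subject <= 1e-12 * max(ss_total, 1.0):
        warning = "between-subject variance is (near) zero; ICC is not informative"
    elif value <= 0:
        warning = "non-positive ICC: rater disagreement exceeds subject variance"
    return ICCResult(value=float(value), model=model, warning=warning)


@dataclass(frozen=True)
class BlandAltman:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int


def bland_altman(a, b, *, loa_multiplier: float = LOA_MULTIPLIER) -> BlandAltman:
    """Bland-Altman paired-difference statistics for a - b."""
    a, b = _paired(a, b, min_n=2)
    d = a - b
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltman(
        bias=bias,
        sd_diff=sd,
        loa_low=bias - loa_multiplier * sd,
        loa_high=bias + loa_multiplier * sd,
        n=d.size,
    )


def ols_fit(x, y) -> tuple[float, float, float]:
    """Least-squares line y = slope*x + intercept and the Pearson r."""
    x, y = _paired(x, y, min_n=3)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: regression is degenerate")
    res = stats.linregress(x, y)
    return float(res.slope), float(res.intercept), float(res.rvalue)


@dataclass(frozen=True)
class PairedTest:
    statistic: float
    p_value: float
    kind: str
    degenerate: bool = False


def paired_compare(a, b, kind: str = "t") -> PairedTest:
    """Paired t-test (parametric) or Wilcoxon signed-rank test."""
    a, b = _paired(a, b, min_n=3)
    d = a - b
    if kind == "t":
        if np.ptp(d) == 0 and d[0] == 0:
            return PairedTest(statistic=0.0, p_value=1.0, kind="t", degenerate=True)
        res = stats.ttest_rel(a, b)
        return PairedTest(statistic=float(res.statistic), p_value=float(res.pvalue), kind="t")
    if kind == "wilcoxon":
        if np.all(d == 0):
            return PairedTest(
                statistic=float("nan"), p_value=float("nan"),
                kind="wilcoxon", degenerate=True,
            )
        res = stats.wilcoxon(a, b)
        return PairedTest(
            statistic=float(res.statistic), p_value=float(res.pvalue), kind="wilcoxon"
        )
    raise ValueError(f"kind must be 't' or 'wilcoxon', got {kind!r}")


def compare_methods(
    a,
    b,
    *,
    icc_model: str = "twoway_mixed_consistency",
    loa_multiplier: float = LOA_MULTIPLIER,
) -> AgreementReport:
    """Full agreement battery for paired vectors a (test) vs b (reference)."""
    a, b = _paired(a, b, min_n=3)
    slope, intercept, r = ols_fit(b, a)  # regression of test on reference
    icc_res = icc(np.column_stack([a, b]), model=icc_model)
    ba = bland_altman(a, b, loa_multiplier=loa_multiplier)
    return AgreementReport(
        pearson_r=r,
        icc=icc_res.value,
        icc_model=icc_res.model,
        ols_slope=slope,
        ols_intercept=intercept,
        bias=ba.bias,
        sd_diff=ba.sd_diff,
        loa_low=ba.loa_low,
        loa_high=ba.loa_high,
        n=ba.n,
    )


def agreement_report_frame(pairs: dict, **kwargs) -> pd.DataFrame:
    """One agreement row per named metric; ``pairs`` maps metric name to
    (test_values, reference_values)."""
    rows = []
    for name, (a, b) in pairs.items():
        rows.append({"metric": name, **compare_methods(a, b, **kwargs).to_dict()})
    return pd.DataFrame(rows)
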