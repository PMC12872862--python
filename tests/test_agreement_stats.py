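"""Agreement statistics: ICC models, Bland-Altman, OLS, paired tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvloops.agreement_stats import (
    bland_altman,
    compare_methods,
    icc,
    ols_fit,
    paired_compare,
)


def _icc_bruteforce(x, model):
    """Independent variance-components oracle: explicit ANOVA sums written
    out score by score."""
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    subj = [sum(x[i]) / k for i in range(n)]
    rater = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_total = sum((x[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_subj = k * sum((s - grand) ** 2 for s in subj)
    ss_rater = n * sum((r - grand) ** 2 for r in rater)
    msb = ss_subj / (n - 1)
    msw = (ss_total - ss_subj) / (n * (k - 1))
    msc = ss_rater / (k - 1)
    mse = (ss_total - ss_subj - ss_rater) / ((n - 1) * (k - 1))
    if model == "oneway_random":
        return (msb - msw) / (msb + (k - 1) * msw)
    if model == "twoway_random":
        return (msb - mse) / (msb + (k - 1) * mse + k * (msc - mse) / n)
    return (msb - mse) / (msb + (k - 1) * mse)


class TestICC:
    @pytest.mark.parametrize(
        "model", ["oneway_random", "twoway_random", "twoway_mixed_consistency"]
    )
    def test_matches_bruteforce_oracle(self, model):
        rng = np.random.default_rng(42)
        for _ in range(5):
            x = rng.normal(10, 2, size=(10, 2)) + rng.normal(0, 3, size=(10, 1))
            assert icc(x, model).value == pytest.approx(
                _icc_bruteforce(x, model), abs=1e-10
            )

    @pytest.mark.parametrize(
        "model", ["oneway_random", "twoway_random", "twoway_mixed_consistency"]
    )
    def test_matches_pingouin(self, model):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(7)
        x = rng.normal(10, 2, size=(12, 2)) + rng.normal(0, 4, size=(12, 1))
        df = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(12), 2),
                "raters": np.tile([0, 1], 12),
                "ratings": x.ravel(),
            }
        )
        res = pg.intraclass_corr(df, targets="targets", raters="raters", ratings="ratings")
        row = {"oneway_random": 0, "twoway_random": 1, "twoway_mixed_consistency": 2}[model]
        assert icc(x, model).value == pytest.approx(float(res["ICC"].iloc[row]), abs=1e-12)

    def test_consistency_ignores_constant_offset(self):
        rng = np.random.default_rng(1)
        a = rng.normal(50, 10, 15)
        x = np.column_stack([a, a + 7.5])
        assert icc(x, "twoway_mixed_consistency").value == pytest.approx(1.0, abs=1e-12)
        # absolute-agreement two-way random model is penalized by the offset
        assert icc(x, "twoway_random").value < 1.0

    def test_identical_raters_give_one(self):
        a = np.arange(3, 13, dtype=float)
        x = np.column_stack([a, a])
        for model in ("oneway_random", "twoway_random", "twoway_mixed_consistency"):
            assert icc(x, model).value == pytest.approx(1.0)

    def test_zero_between_subject_variance_flagged(self):
        x = np.array([[5.0, 6.0]] * 8)
        res = icc(x, "oneway_random")
        assert res.value <= 0
        assert res.warning is not None


class TestBlandAltman:
    def test_identical_vectors(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = bland_altman(a, a)
        assert res.bias == 0 and res.sd_diff == 0
        assert res.loa_low == 0 and res.loa_high == 0

    def test_constant_shift(self):
        a = np.array([1.0, 2.0, 3.0])
        res = bland_altman(a + 5, a)
        assert res.bias == pytest.approx(5.0)
        assert res.sd_diff == 0

    def test_loa_identity(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 30), rng.normal(0, 1, 30)
        res = bland_altman(a, b)
        assert res.loa_low == pytest.approx(res.bias - 1.96 * res.sd_diff)
        assert res.loa_high == pytest.approx(res.bias + 1.96 * res.sd_diff)

    def test_monte_carlo_recovers_generator_bias(self):
        """Differences drawn at the validation study's scale: bias estimate
        within a few standard errors of the generating mean."""
        rng = np.random.default_rng(5)
        b = rng.uniform(8000, 20000, 1000)
        a = b + rng.normal(-549, 774, 1000)
        res = bland_altman(a, b)
        assert res.bias == pytest.approx(-549, abs=50)  # ~2 SE
        assert res.sd_diff == pytest.approx(774, rel=0.1)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_swap_antisymmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(0, 1, 10), rng.normal(0, 1, 10)
        ab, ba = bland_altman(a, b), bland_altman(b, a)
        assert ab.bias == pytest.approx(-ba.bias)
        assert ab.loa_high - ab.loa_low == pytest.approx(ba.loa_high - ba.loa_low)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            bland_altman([1, 2, 3], [1, 2])


class TestOLS:
    def test_exact_line(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        slope, intercept, r = ols_fit(x, 2 * x + 1)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(1.0)
        assert r == pytest.approx(1.0)

    def test_anticorrelation(self):
        x = np.linspace(0, 1, 10)
        _, _, r = ols_fit(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(11)
        x = rng.uniform(0, 10, 40)
        y = 3 * x - 2 + rng.normal(0, 1, 40)
        slope, intercept, _ = ols_fit(x, y)
        A = np.column_stack([x, np.ones_like(x)])
        coef = np.linalg.solve(A.T @ A, A.T @ y)
        assert slope == pytest.approx(coef[0], abs=1e-9)
        assert intercept == pytest.approx(coef[1], abs=1e-9)

    def test_degenerate_x(self):
        with pytest.raises(ValueError, match="degenerate"):
            ols_fit([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestPairedCompare:
    def test_identical_gives_zero_t(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_compare(a, a, kind="t")
        assert res.statistic == 0.0
        assert res.degenerate

    def test_wilcoxon_all_zero_flagged(self):
        a = np.array([1.0, 2.0, 3.0])
        res = paired_compare(a, a, kind="wilcoxon")
        assert res.degenerate

    def test_t_matches_textbook_formula(self):
        rng = np.random.default_rng(9)
        a = rng.normal(10, 2, 20)
        b = a + rng.normal(0.5, 1, 20)
        res = paired_compare(a, b, kind="t")
        d = a - b
        expected = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert res.statistic == pytest.approx(expected, abs=1e-9)


class TestCompareMethods:
    def test_self_comparison(self):
        rng = np.random.default_rng(2)
        a = rng.uniform(5000, 20000, 16)
        rep = compare_methods(a, a.copy())
        assert rep.pearson_r == pytest.approx(1.0)
        assert rep.icc == pytest.approx(1.0)
        assert rep.bias == 0.0
        assert rep.n == 16

    def test_loa_invariant(self):
        rng = np.random.default_rng(3)
        b = rng.uniform(5000, 20000, 16)
        a = 0.9 * b + rng.normal(0, 500, 16)
        rep = compare_methods(a, b)
        assert rep.loa_low == pytest.approx(rep.bias - 1.96 * rep.sd_diff)
        assert rep.loa_high == pytest.approx(rep.bias + 1.96 * rep.sd_diff)
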