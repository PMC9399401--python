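import math

import numpy as np
import pingouin as pg
import pandas as pd
import pytest

from gaitlift._errors import DataError, DegenerateError
from gaitlift.agreement_stats import (band, bland_altman, compare_tables,
                                      difference_test, icc, sem_sdc)


def _ratings(rng, n=30, subject_sd=1.0, error_sd=0.3, offset=0.0):
    s = rng.normal(0, subject_sd, n)
    return np.column_stack([
        s + rng.normal(0, error_sd, n),
        s + offset + rng.normal(0, error_sd, n),
    ])


class TestIcc:
    def test_identical_ratings_both_forms_one(self, rng):
        x = rng.normal(size=10)
        data = np.column_stack([x, x])
        assert icc(data, "C1").estimate == pytest.approx(1.0)
        assert icc(data, "A1").estimate == pytest.approx(1.0)

    def test_constant_offset_consistency_vs_agreement(self, rng):
        x = rng.normal(size=12)
        data = np.column_stack([x, x + 10.0])
        assert icc(data, "C1").estimate == pytest.approx(1.0)
        assert icc(data, "A1").estimate < 1.0

    def test_six_subject_integer_fixture_anova_oracle(self):
        # hand-evaluated two-way ANOVA mean squares for this 6 x 2 table
        data = np.array([[1, 2], [3, 4], [5, 7], [2, 2], [4, 6], [6, 8]],
                        dtype=float)
        n, k = data.shape
        grand = data.mean()
        msr = k * ((data.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((data.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        mse = ((data - data.mean(axis=1, keepdims=True)
                - data.mean(axis=0, keepdims=True) + grand) ** 2).sum() \
            / ((n - 1) * (k - 1))
        expected_c1 = (msr - mse) / (msr + (k - 1) * mse)
        expected_a1 = (msr - mse) / (msr + (k - 1) * mse
                                     + k / n * (msc - mse))
        assert icc(data, "C1").estimate == pytest.approx(expected_c1,
                                                         abs=1e-12)
        assert icc(data, "A1").estimate == pytest.approx(expected_a1,
                                                         abs=1e-12)

    def test_matches_pingouin_estimates_and_ci(self, rng):
        data = _ratings(rng, n=25, offset=0.4)
        long = pd.DataFrame({
            "subject": np.repeat(np.arange(25), 2),
            "rater": np.tile(["a", "b"], 25),
            "score": data.ravel(),
        })
        table = pg.intraclass_corr(long, targets="subject", raters="rater",
                                   ratings="score").set_index("Type")
        ours_a1 = icc(data, "A1")
        ours_c1 = icc(data, "C1")
        assert ours_a1.estimate == pytest.approx(
            table.loc["ICC(A,1)", "ICC"], abs=1e-9)
        assert ours_c1.estimate == pytest.approx(
            table.loc["ICC(C,1)", "ICC"], abs=1e-9)
        ci2 = table.loc["ICC(A,1)", "CI95"]
        assert ours_a1.ci_lower == pytest.approx(ci2[0], abs=0.01)
        assert ours_a1.ci_upper == pytest.approx(ci2[1], abs=0.01)

    def test_estimate_inside_ci_and_narrows_with_n(self, rng):
        res_small = icc(_ratings(rng, n=8), "A1")
        res_large = icc(_ratings(rng, n=200), "A1")
        for res in (res_small, res_large):
            assert res.ci_lower <= res.estimate <= res.ci_upper
        assert (res_large.ci_upper - res_large.ci_lower
                < res_small.ci_upper - res_small.ci_lower)

    def test_zero_between_subject_variance_undefined(self):
        data = np.tile([2.0, 2.0], (5, 1))
        with pytest.raises(DegenerateError):
            icc(data, "A1")

    def test_variance_component_recovery(self):
        rng = np.random.default_rng(99)
        sigma_s2, sigma_e2 = 1.5, 1.0
        n = 5000
        s = rng.normal(0, math.sqrt(sigma_s2), n)
        data = np.column_stack([s + rng.normal(0, 1, n),
                                s + rng.normal(0, 1, n)])
        expected = sigma_s2 / (sigma_s2 + sigma_e2)
        assert icc(data, "A1").estimate == pytest.approx(expected, abs=0.03)


class TestSemSdc:
    def test_sdc_from_sem_constant(self):
        # SEM = 0.02 must give SDC = 1.96 * sqrt(2) * 0.02 = 0.05544
        assert 1.96 * math.sqrt(2) * 0.02 == pytest.approx(0.05544, abs=1e-5)

    def test_sdc_is_fixed_multiple_of_sem(self, rng):
        sem, sdc = sem_sdc(_ratings(rng))
        assert sdc == pytest.approx(1.96 * math.sqrt(2) * sem, abs=1e-12)

    def test_perfect_agreement_zero_sem(self, rng):
        x = rng.normal(size=10)
        sem, sdc = sem_sdc(np.column_stack([x, x]))
        assert sem == pytest.approx(0.0, abs=1e-6)
        assert sdc == pytest.approx(0.0, abs=1e-6)

    def test_scale_equivariance(self, rng):
        data = _ratings(rng)
        sem1, sdc1 = sem_sdc(data)
        sem2, sdc2 = sem_sdc(2.0 * data)
        assert sem2 == pytest.approx(2 * sem1, rel=1e-9)
        assert sdc2 == pytest.approx(2 * sdc1, rel=1e-9)


class TestBlandAltman:
    def test_identical_series(self, rng):
        a = rng.normal(size=10)
        res = bland_altman(a, a.copy())
        assert res.bias == 0.0
        assert res.loa_lower == res.loa_upper == 0.0
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_loa(self):
        a = np.array([10.0, 20.0, 30.0])
        b = a - np.array([-1.0, 0.0, 1.0])
        res = bland_altman(a, b)
        assert res.bias == pytest.approx(0.0)
        sd = np.std([-1.0, 0.0, 1.0], ddof=1)
        assert res.loa_upper == pytest.approx(1.96 * sd, abs=1e-12)
        assert res.loa_lower == pytest.approx(-1.96 * sd, abs=1e-12)

    def test_constructed_proportional_bias_slope(self, rng):
        mean = np.linspace(10, 30, 20)
        diff = 0.1 * mean
        a = mean + diff / 2
        b = mean - diff / 2
        res = bland_altman(a, b)
        assert res.slope == pytest.approx(0.1, abs=1e-9)

    def test_loa_coverage_asymptotic(self):
        rng = np.random.default_rng(7)
        diff = rng.normal(0.3, 1.7, 100_000)
        a = diff
        b = np.zeros_like(diff)
        res = bland_altman(a, b)
        outside = np.mean((diff < res.loa_lower) | (diff > res.loa_upper))
        assert outside == pytest.approx(0.05, abs=0.005)


class TestDifferenceTest:
    def test_identical_groups_t_test_p_one(self, rng):
        x = rng.normal(size=20)
        res = difference_test(x, x.copy(), paired=False)
        assert res.test_name == "independent t-test"
        assert res.p_value > 0.99

    def test_skewed_group_selects_wilcoxon(self):
        rng = np.random.default_rng(13)
        a = rng.exponential(1.0, 40)
        b = rng.normal(1.0, 0.5, 40)
        res = difference_test(a, b, paired=False)
        assert not res.gates_passed
        assert res.test_name == "wilcoxon rank-sum"

    def test_bonferroni_product(self, rng):
        a = rng.normal(0.0, 1.0, 30)
        b = rng.normal(0.8, 1.0, 30)
        res = difference_test(a, b, paired=False, comparisons=10)
        assert res.p_adjusted == pytest.approx(min(1.0, res.p_value * 10))

    def test_paired_uses_signed_rank_when_gates_fail(self):
        rng = np.random.default_rng(13)
        a = rng.exponential(1.0, 40)
        b = a + rng.normal(0, 0.2, 40)
        res = difference_test(a, b, paired=True)
        assert res.test_name in ("wilcoxon signed-rank", "paired t-test")
        if not res.gates_passed:
            assert res.test_name == "wilcoxon signed-rank"


class TestBand:
    @pytest.mark.parametrize("value,label", [
        (0.734, "substantial"),
        (0.81, "almost perfect"),
        (0.20, "slight"),
        (0.21, "fair"),
        (0.41, "moderate"),
        (0.61, "substantial"),
        (1.0, "almost perfect"),
        (0.0, "slight"),
        (-0.2, "below slight"),
    ])
    def test_cutpoints(self, value, label):
        assert band(value) == label


class TestCompareTables:
    def _table(self, rng, n=6):
        return pd.DataFrame(
            rng.normal(1.0, 0.3, size=(n, 3)),
            columns=["RTS", "RUX", "RTX"],
            index=[f"p{i}" for i in range(n)])

    def test_self_comparison_perfect(self, rng):
        t = self._table(rng)
        report = compare_tables(t, t.copy(), "cross_system")
        for entry in report.angles:
            assert entry.icc == pytest.approx(1.0)
            assert entry.bias == pytest.approx(0.0)

    def test_mode_column_contract(self, rng):
        t = self._table(rng)
        u = t + rng.normal(0, 0.05, t.shape)
        retest = compare_tables(t, u, "test_retest").to_frame()
        cross = compare_tables(t, u, "cross_system").to_frame()
        assert "sdc" not in retest.columns
        assert "sdc" in cross.columns
        assert len(retest) == len(cross) == 3

    def test_misaligned_participants_rejected(self, rng):
        t = self._table(rng)
        u = self._table(rng)
        u.index = [f"q{i}" for i in range(len(u))]
        with pytest.raises(DataError):
            compare_tables(t, u)
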