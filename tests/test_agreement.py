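import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from accdetect import bland_altman, ccc, repeatability
from accdetect.reference import (
    METHOD_COMPARISON_LOA,
    REPEATABILITY_LOA,
    REPORTED_COR,
    cor_from_loa,
    loa_midpoint_deviation,
)


class TestBlandAltman:
    def test_identity_input(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        with pytest.warns(UserWarning, match="zero variance"):
            out = bland_altman(x, x)
        assert out.bias == 0.0 and out.sd_diff == 0.0
        assert out.loa_lower == out.loa_upper == 0.0

    def test_limits_symmetric_about_bias(self, rng):
        x = rng.normal(5, 2, 50)
        y = rng.normal(4, 2, 50)
        out = bland_altman(x, y)
        assert (out.loa_upper - out.bias) == pytest.approx(out.bias - out.loa_lower)
        assert (out.loa_upper - out.loa_lower) == pytest.approx(2 * 1.96 * out.sd_diff)

    def test_swap_negates_bias_and_limits(self, rng):
        x = rng.normal(0, 1, 30)
        y = rng.normal(1, 1, 30)
        a = bland_altman(x, y)
        b = bland_altman(y, x)
        assert b.bias == pytest.approx(-a.bias)
        assert b.loa_lower == pytest.approx(-a.loa_upper)
        assert b.loa_upper == pytest.approx(-a.loa_lower)

    def test_coverage_of_gaussian_differences(self, rng):
        """~95 % of Normal(0,1) differences fall inside the limits of agreement."""
        d = rng.standard_normal(10_000)
        x = d
        y = np.zeros_like(d)
        out = bland_altman(x, y)
        inside = np.mean((d >= out.loa_lower) & (d <= out.loa_upper))
        assert inside == pytest.approx(0.95, abs=0.01)

    def test_missing_pairs_dropped(self):
        x = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
        y = np.array([1.5, 2.0, np.nan, 4.0, 5.5])
        out = bland_altman(x, y)
        assert out.n == 3

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0, 2.0])

    def test_bias_ci_uses_t_distribution(self, rng):
        x = rng.normal(0, 1, 12)
        y = rng.normal(0, 1, 12)
        out = bland_altman(x, y)
        t = stats.t.ppf(0.975, 11)
        half = t * out.sd_diff / np.sqrt(12)
        assert out.ci_bias[1] - out.bias == pytest.approx(half)
        half_loa = t * np.sqrt(3 * out.sd_diff**2 / 12)
        assert out.ci_loa_upper[1] - out.loa_upper == pytest.approx(half_loa)

    def test_repeated_correction_recovers_variance_components(self, rng):
        """With per-subject offsets, the corrected SD ~ sqrt(between + within)."""
        n_subj, n_rep = 60, 2
        sigma_b, sigma_w = 2.0, 1.0
        subj_effect = rng.normal(0, sigma_b, n_subj)
        d = (subj_effect[:, None] + rng.normal(0, sigma_w, (n_subj, n_rep))).ravel()
        subjects = np.repeat(np.arange(n_subj), n_rep)
        out = bland_altman(d, np.zeros_like(d), repeated=True, subjects=subjects)
        assert out.sd_diff == pytest.approx(np.sqrt(sigma_b**2 + sigma_w**2), rel=0.15)

    def test_repeated_without_subjects_warns_and_falls_back(self, rng):
        x = rng.normal(0, 1, 10)
        y = rng.normal(0, 1, 10)
        with pytest.warns(UserWarning, match="subject labels"):
            out = bland_altman(x, y, repeated=True)
        plain = bland_altman(x, y)
        assert out.sd_diff == pytest.approx(plain.sd_diff)


class TestRepeatability:
    def test_identical_repetitions_zero_cor(self):
        x = np.array([3.0, 6.0, 9.0, 12.0])
        with pytest.warns(UserWarning, match="zero variance"):
            out = repeatability(x, x)
        assert out.cor == 0.0

    def test_alternating_differences(self):
        """Differences (-1, +1, -1, +1): SD = 1.1547, CoR = 2.309."""
        rep1 = np.array([0.0, 1.0, 0.0, 1.0])
        rep2 = np.array([1.0, 0.0, 1.0, 0.0])
        with pytest.warns(UserWarning, match="subject labels"):
            out = repeatability(rep1, rep2)
        assert out.sd_diff == pytest.approx(1.1547, abs=1e-4)
        assert out.cor == pytest.approx(2.309, abs=1e-3)

    def test_cor_is_twice_sd(self, rng):
        r1 = rng.normal(6, 3, 20)
        r2 = rng.normal(6, 3, 20)
        out = repeatability(r1, r2, subjects=np.arange(20))
        assert out.cor == pytest.approx(2.0 * out.sd_diff)


class TestPublishedTables:
    def test_cor_back_derivation_matches_reported_values(self):
        """CoR from printed limits reproduces the four reported coefficients."""
        for key, row in REPEATABILITY_LOA.items():
            got = cor_from_loa(row["loa_lower"][0], row["loa_upper"][0])
            assert got == pytest.approx(REPORTED_COR[key], abs=0.02), key

    def test_printed_loa_midpoints_equal_printed_bias(self):
        assert loa_midpoint_deviation(METHOD_COMPARISON_LOA) <= 0.02
        assert loa_midpoint_deviation(REPEATABILITY_LOA) <= 0.02


class TestCCC:
    def test_identity_gives_one(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        out = ccc(x, x)
        assert out.estimate == pytest.approx(1.0)

    def test_worked_four_point_example(self):
        """x=(1..4), y=x+1: s_xy = 1.25, variances 1.25, shift 1 -> 5/7."""
        out = ccc([1.0, 2.0, 3.0, 4.0], [2.0, 3.0, 4.0, 5.0])
        assert out.estimate == pytest.approx(5.0 / 7.0, abs=1e-9)

    def test_anti_agreement_negative(self, rng):
        x = rng.normal(0, 1, 40)
        out = ccc(x, -x + 0.3)
        assert out.estimate < 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ccc([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_pearson_decomposition(self, rng):
        """ccc = r * 2*sx*sy / (sx^2 + sy^2 + (mx-my)^2), with scipy's r."""
        x = rng.normal(2, 1.5, 35)
        y = 0.8 * x + rng.normal(1, 0.7, 35)
        out = ccc(x, y)
        r = stats.pearsonr(x, y).statistic
        sx, sy = x.std(), y.std()
        expected = r * 2 * sx * sy / (sx**2 + sy**2 + (x.mean() - y.mean()) ** 2)
        assert out.estimate == pytest.approx(expected, rel=1e-9)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(shift=st.floats(-3, 3), scale=st.floats(0.3, 3.0),
           seed=st.integers(0, 1000))
    def test_magnitude_bounded_by_pearson_r(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 25)
        y = scale * x + shift + rng.normal(0, 0.5, 25)
        out = ccc(x, y)
        r = abs(stats.pearsonr(x, y).statistic)
        assert -1.0 <= out.estimate <= 1.0
        assert abs(out.estimate) <= r + 1e-12

    def test_ci_contains_estimate_and_orders(self, rng):
        x = rng.normal(0, 1, 30)
        y = x + rng.normal(0, 0.5, 30)
        out = ccc(x, y)
        assert out.ci[0] <= out.estimate <= out.ci[1]

    def test_bootstrap_ci_close_to_analytic(self, rng):
        x = rng.normal(0, 1, 60)
        y = x + rng.normal(0, 0.6, 60)
        ana = ccc(x, y)
        boot = ccc(x, y, n_boot=500, seed=1)
        assert boot.ci[0] == pytest.approx(ana.ci[0], abs=0.12)
        assert boot.ci[1] == pytest.approx(ana.ci[1], abs=0.12)
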