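"""Repeatability statistics: ICC, Bland-Altman, t-tests, correlations."""

import numpy as np
import pingouin as pg
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import special

from cranioflow.repstats import (
    PairedMeasurements,
    bland_altman,
    conformity_result,
    grade_icc,
    group_compare,
    icc_absolute_agreement,
    icc_consistency,
    paired_t,
    pearson,
    repeatability_result,
    significance_stars,
    size_vs_error,
)


def icc_a1_oracle(a, b):
    """ICC(A,1) from explicitly accumulated sums of squares (scalar loops)."""
    x = [[float(p), float(q)] for p, q in zip(a, b)]
    n, k = len(x), 2
    grand = sum(sum(row) for row in x) / (n * k)
    row_means = [sum(row) / k for row in x]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_r = k * sum((m - grand) ** 2 for m in row_means)
    ss_c = n * sum((m - grand) ** 2 for m in col_means)
    ss_e = sum((x[i][j] - row_means[i] - col_means[j] + grand) ** 2
               for i in range(n) for j in range(k))
    ms_r = ss_r / (n - 1)
    ms_c = ss_c / (k - 1)
    ms_e = ss_e / ((n - 1) * (k - 1))
    return (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e))


FIXED_DATASETS = [
    ([1.0, 2.0, 3.0, 4.0], [1.1, 2.0, 3.2, 3.9]),
    ([10.0, 12.0, 15.0, 11.0, 14.0], [11.0, 13.0, 14.5, 12.0, 13.5]),
    ([0.5, 0.9, 1.4, 2.0, 2.2, 3.1], [0.4, 1.1, 1.2, 2.3, 2.0, 3.3]),
    ([5.0, 5.5, 6.0, 6.5], [7.0, 7.5, 8.0, 8.5]),  # pure offset
    ([2.0, 4.0, 6.0, 8.0, 10.0], [2.2, 3.7, 6.3, 7.8, 10.4]),
]


class TestICC:
    @pytest.mark.parametrize("a,b", FIXED_DATASETS)
    def test_matches_hand_computed_mean_squares(self, a, b):
        pm = PairedMeasurements(a=np.array(a), b=np.array(b))
        assert icc_absolute_agreement(pm) == pytest.approx(icc_a1_oracle(a, b),
                                                           abs=1e-10)

    @pytest.mark.parametrize("a,b", FIXED_DATASETS)
    def test_matches_pingouin_icc2(self, a, b):
        import pandas as pd

        df = pd.DataFrame({
            "subject": list(range(len(a))) * 2,
            "rater": ["s1"] * len(a) + ["s2"] * len(a),
            "score": list(a) + list(b),
        })
        ref = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score")
        icc2 = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        pm = PairedMeasurements(a=np.array(a), b=np.array(b))
        assert icc_absolute_agreement(pm) == pytest.approx(icc2, abs=1e-8)

    def test_identical_sessions_give_one(self):
        pm = PairedMeasurements(a=np.array([1.0, 2.0, 3.0, 4.0]),
                                b=np.array([1.0, 2.0, 3.0, 4.0]))
        assert icc_absolute_agreement(pm) == pytest.approx(1.0)

    def test_absolute_agreement_penalises_offset(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        pm = PairedMeasurements(a=a, b=a + 10.0)
        assert icc_absolute_agreement(pm) < 1.0
        # the consistency form ignores the offset
        assert icc_consistency(pm) == pytest.approx(1.0)

    def test_no_variance_reported_missing(self):
        pm = PairedMeasurements(a=np.full(4, 2.0), b=np.full(4, 2.0))
        assert np.isnan(icc_absolute_agreement(pm))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            icc_absolute_agreement(PairedMeasurements(a=np.array([1.0, 2.0]),
                                                      b=np.array([1.0, 2.0])))

    @given(st.floats(0.1, 5.0), st.floats(-10.0, 10.0))
    def test_invariant_under_common_affine_rescaling(self, scale, shift):
        a = np.array([1.0, 2.0, 3.0, 4.5, 6.0])
        b = np.array([1.2, 1.9, 3.3, 4.2, 6.2])
        pm1 = PairedMeasurements(a=a, b=b)
        pm2 = PairedMeasurements(a=scale * a + shift, b=scale * b + shift)
        assert icc_absolute_agreement(pm2) == pytest.approx(
            icc_absolute_agreement(pm1), abs=1e-9)

    @given(st.integers(0, 10_000))
    def test_never_exceeds_one(self, seed):
        r = np.random.default_rng(seed)
        a, b = r.normal(size=6), r.normal(size=6)
        assert icc_absolute_agreement(PairedMeasurements(a=a, b=b)) <= 1.0 + 1e-12


class TestGradeICC:
    @pytest.mark.parametrize("icc,grade", [
        (0.765, "good"),
        (0.226, "poor"),
        (0.912, "excellent"),
        (0.49999, "poor"),
        (0.5, "moderate"),
        (0.75, "good"),
        (0.9, "good"),
        (0.90001, "excellent"),
        (-0.2, "poor"),
    ])
    def test_bins(self, icc, grade):
        assert grade_icc(icc) == grade

    def test_non_finite(self):
        assert grade_icc(float("nan")) == "undefined"


class TestBlandAltman:
    def test_constant_shift(self):
        pm = PairedMeasurements(a=np.array([1.0, 2.0, 3.0]), b=np.array([2.0, 3.0, 4.0]))
        ba = bland_altman(pm)
        assert ba["mean_diff"] == pytest.approx(1.0)
        assert ba["sd_diff"] == pytest.approx(0.0)
        assert ba["loa_low"] == pytest.approx(1.0)
        assert ba["loa_high"] == pytest.approx(1.0)

    def test_identical_arms_all_zero(self):
        a = np.array([1.0, 5.0, 9.0])
        ba = bland_altman(PairedMeasurements(a=a, b=a.copy()))
        assert ba["mean_diff"] == 0.0 and ba["loa_high"] == 0.0

    def test_percentage_relative_to_first_arm(self):
        ba = bland_altman(PairedMeasurements(a=np.array([60.0, 50.0]),
                                             b=np.array([63.0, 50.0])))
        np.testing.assert_allclose(ba["pct_diffs"], [5.0, 0.0])

    def test_zero_baseline_percentage_missing(self):
        ba = bland_altman(PairedMeasurements(a=np.array([0.0, 2.0, 4.0]),
                                             b=np.array([1.0, 2.0, 4.0])))
        assert np.isnan(ba["pct_diffs"][0])

    def test_loa_coverage_near_95pct(self, rng):
        # 1.96 SD limits hold >= 93% of differences in a large Gaussian sample
        a = rng.normal(10.0, 2.0, size=5000)
        b = a + rng.normal(0.3, 0.8, size=5000)
        ba = bland_altman(PairedMeasurements(a=a, b=b))
        inside = np.mean((ba["diffs"] >= ba["loa_low"]) & (ba["diffs"] <= ba["loa_high"]))
        assert inside >= 0.93


class TestPairedT:
    def test_symmetric_diffs_give_t_zero(self):
        pm = PairedMeasurements(a=np.array([1.0, 2.0, 3.0, 4.0]),
                                b=np.array([2.0, 1.0, 4.0, 3.0]))
        t, p, degen = paired_t(pm)
        assert not degen
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_constant_shift_degenerate(self):
        pm = PairedMeasurements(a=np.array([1.0, 2.0, 3.0]), b=np.array([2.0, 3.0, 4.0]))
        t, p, degen = paired_t(pm)
        assert degen and np.isnan(t) and np.isnan(p)

    def test_p_matches_t_cdf_oracle(self, rng):
        diffs = rng.normal(0.0, 1.0, size=10)
        a = rng.normal(5.0, 1.0, size=10)
        pm = PairedMeasurements(a=a, b=a + diffs)
        t, p, _ = paired_t(pm)
        n = 10
        t_ref = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(n))
        # two-sided p from the regularised incomplete beta (t CDF identity)
        df = n - 1
        p_ref = special.betainc(df / 2.0, 0.5, df / (df + t_ref**2))
        assert t == pytest.approx(t_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)


class TestPearson:
    def test_perfect_linear(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        r, p = pearson(PairedMeasurements(a=a, b=2 * a + 1))
        assert r == pytest.approx(1.0)

    def test_orthogonal_gives_zero(self):
        a = np.array([-1.0, 0.0, 1.0, 0.0])
        b = np.array([0.0, 1.0, 0.0, -1.0])
        r, _ = pearson(PairedMeasurements(a=a, b=b))
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_small_fixed_vector_covariance_formula(self):
        a = np.array([1.0, 2.0, 4.0, 5.0, 7.0])
        b = np.array([2.0, 3.5, 3.0, 6.0, 8.0])
        r, p = pearson(PairedMeasurements(a=a, b=b))
        am, bm = a - a.mean(), b - b.mean()
        r_ref = (am @ bm) / np.sqrt((am @ am) * (bm @ bm))
        assert r == pytest.approx(r_ref, abs=1e-12)
        t_ref = r_ref * np.sqrt(3 / (1 - r_ref**2))
        p_ref = special.betainc(1.5, 0.5, 3 / (3 + t_ref**2))
        assert p == pytest.approx(p_ref, abs=1e-10)

    def test_constant_input_undefined(self):
        r, p = pearson(PairedMeasurements(a=np.full(4, 3.0), b=np.array([1.0, 2, 3, 4])))
        assert np.isnan(r) and np.isnan(p)


class TestSizeVsError:
    def test_constant_metric_reported_missing(self):
        r, p = size_vs_error([1.0, 2.0, 3.0], [0.8, 0.8, 0.8])
        assert np.isnan(r)

    def test_inverse_area_error_negative_r(self):
        areas = np.array([2.0, 4.0, 8.0, 16.0])
        r, _ = size_vs_error(areas, 1.0 / areas)
        assert r < 0


class TestGroupCompare:
    def test_identical_groups(self, rng):
        g = rng.normal(size=8)
        s = group_compare(g, g.copy())
        tests = s.attrs["tests"].set_index("test")
        assert tests.loc["welch_t", "p"] == pytest.approx(1.0)

    def test_large_shift_significant(self, rng):
        g = rng.normal(size=10)
        s = group_compare(g, g + 50.0 + rng.normal(0, 0.2, size=10))
        tests = s.attrs["tests"].set_index("test")
        assert tests.loc["paired_t", "p"] < 1e-6
        assert tests.loc["welch_t", "p"] < 1e-6

    def test_welch_p_matches_cdf_oracle(self, rng):
        g1 = rng.normal(0.0, 1.0, size=10)
        g2 = rng.normal(1.0, 1.0, size=10)
        s = group_compare(g1, g2)
        t = s.attrs["tests"].set_index("test").loc["welch_t"]
        v1, v2 = g1.var(ddof=1) / 10, g2.var(ddof=1) / 10
        t_ref = (g2.mean() - g1.mean()) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / 9 + v2**2 / 9)
        p_ref = special.betainc(df / 2, 0.5, df / (df + t_ref**2))
        assert t["stat"] == pytest.approx(t_ref, abs=1e-10)
        assert t["p"] == pytest.approx(p_ref, abs=1e-10)

    def test_mismatched_sizes_skip_paired(self, rng):
        with pytest.warns(UserWarning, match="paired"):
            s = group_compare(rng.normal(size=5), rng.normal(size=7))
        assert "paired_t" not in s.attrs["tests"]["test"].values


class TestResultAssembly:
    def test_stars_consistent_with_p(self):
        assert significance_stars(0.049) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"
        assert significance_stars(0.5) == ""
        assert significance_stars(float("nan")) == ""

    def test_repeatability_result_invariants(self, rng):
        a = rng.normal(10, 2, size=8)
        b = a + rng.normal(0, 0.5, size=8)
        r = repeatability_result(PairedMeasurements(a=a, b=b))
        assert r.loa_low == pytest.approx(r.mean_diff - 1.96 * r.sd_diff)
        assert r.loa_high == pytest.approx(r.mean_diff + 1.96 * r.sd_diff)
        assert r.icc_grade == grade_icc(r.icc)

    def test_conformity_result_fields(self, rng):
        a = rng.normal(10, 2, size=8)
        b = a * 1.1 + rng.normal(0, 0.3, size=8)
        c = conformity_result(PairedMeasurements(a=a, b=b))
        assert -1.0 <= c.pearson_r <= 1.0
        assert c.n == 8

    def test_listwise_deletion(self):
        pm = PairedMeasurements(a=np.array([1.0, np.nan, 3.0, 4.0]),
                                b=np.array([1.0, 2.0, np.nan, 4.0]))
        assert pm.n == 2
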