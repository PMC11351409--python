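import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from qvor.cohort_stats import (
    age_bin_label,
    anova_by_groups,
    compare_groups,
    compute_percentiles,
    summarize_cohort,
)
from qvor.cohort_stats import test_frequency_vs_target as frequency_vs_target
from qvor.cohort_stats import test_normality as normality_test
from qvor.errors import InsufficientDataError, ValidationError


def _cohort_df(n=83, n_female=41, si_mean=0.295, si_sd=0.104, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "sex": ["F"] * n_female + ["M"] * (n - n_female),
            "age": rng.uniform(18, 85, n),
            "si_bilateral": rng.normal(si_mean, si_sd, n),
        }
    )


class TestSummaries:
    def test_identical_records_have_zero_sd(self):
        df = pd.DataFrame({"sex": ["F"] * 5, "age": [30] * 5, "x": [0.3] * 5})
        (summary,) = summarize_cohort(df, ["x"])
        assert summary.sd == 0.0
        assert summary.mean == pytest.approx(0.3)

    def test_large_sample_mean_recovery(self):
        df = _cohort_df(n=10000, n_female=5000, seed=1)
        (summary,) = summarize_cohort(df, ["si_bilateral"])
        assert summary.mean == pytest.approx(0.295, abs=0.005)

    def test_sex_grouping_sizes(self):
        df = _cohort_df()
        by_sex = summarize_cohort(df, ["si_bilateral"], group_by="sex")
        sizes = {s.group: s.n for s in by_sex}
        assert sizes == {"F": 41, "M": 42}

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValidationError):
            summarize_cohort(pd.DataFrame(), ["x"])

    def test_age_bin_labels(self):
        assert age_bin_label(20) == "<=20"
        assert age_bin_label(21) == "21-30"
        assert age_bin_label(80) == "71-80"
        assert age_bin_label(81) == ">80"


class TestNormality:
    def test_normal_sample_not_rejected(self):
        rng = np.random.default_rng(2)
        res = normality_test(rng.normal(size=1000))
        assert res.p_value > 0.05

    def test_heavy_asymmetry_rejected(self):
        rng = np.random.default_rng(3)
        skewed = np.exp(4.0 * rng.uniform(size=1000))
        res = normality_test(skewed)
        assert res.p_value < 0.01

    def test_tiny_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            normality_test([1.0, 2.0, 3.0])


class TestFrequencyTest:
    def test_on_target_frequencies_degenerate(self):
        res = frequency_vs_target([0.75] * 20)
        assert res.degenerate
        assert res.p_value == 1.0

    def test_metronome_overshoot_detected(self):
        rng = np.random.default_rng(4)
        freqs = rng.normal(0.825, 0.02, 83)
        res = frequency_vs_target(freqs)
        assert res.p_value < 0.001
        assert res.effect == pytest.approx(0.075, abs=0.01)

    def test_student_t_variant(self):
        rng = np.random.default_rng(4)
        freqs = rng.normal(0.825, 0.02, 83)
        res = frequency_vs_target(freqs, method="ttest")
        assert res.p_value < 0.001

    def test_tiny_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            frequency_vs_target([0.8] * 5)


class TestCompareGroups:
    def test_identical_groups(self):
        res = compare_groups([1.0, 2.0, 3.0, 1.0, 2.0, 3.0],
                             ["a"] * 3 + ["b"] * 3)
        assert res.effect == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_effect_is_antisymmetric_under_label_swap(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        labels = ["a"] * 20 + ["b"] * 20
        swapped = ["b"] * 20 + ["a"] * 20
        r1 = compare_groups(x, labels)
        r2 = compare_groups(x, swapped)
        assert r1.effect == pytest.approx(-r2.effect)

    def test_power_at_cohort_scale(self):
        """Rejection rate for the observed-scale sex difference, reported not asserted
        to a knife edge: the scenario has moderate power, well above alpha."""
        rng = np.random.default_rng(6)
        rejections = 0
        n_rep = 200
        for _ in range(n_rep):
            f = rng.normal(0.27, 0.10, 41)
            m = rng.normal(0.32, 0.10, 42)
            res = compare_groups(
                np.concatenate([f, m]), ["F"] * 41 + ["M"] * 42
            )
            rejections += res.p_value < 0.05
        assert 0.2 < rejections / n_rep < 0.95

    def test_single_group_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([1.0, 2.0], ["a", "a"])


class TestAnova:
    def test_type_one_error_under_null(self):
        rng = np.random.default_rng(7)
        ok = 0
        for _ in range(100):
            x = rng.normal(size=60)
            labels = np.repeat(["a", "b", "c"], 20)
            _, anova = anova_by_groups(x, labels)
            ok += anova.p_value > 0.05
        assert ok >= 90

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(8)
        x = np.concatenate([rng.normal(0, 1, 20), rng.normal(3, 1, 20),
                            rng.normal(0, 1, 20)])
        labels = np.repeat(["a", "b", "c"], 20)
        levene, anova = anova_by_groups(x, labels)
        assert anova.p_value < 0.01
        assert 0 <= levene.p_value <= 1

    def test_singleton_groups_rejected(self):
        with pytest.raises(ValidationError):
            anova_by_groups([1.0, 2.0], ["a", "b"])


class TestPercentiles:
    def test_median_of_integer_ramp(self):
        pct = compute_percentiles(np.arange(1, 100))
        assert pct[50.0] == pytest.approx(50.0)

    def test_constant_vector(self):
        pct = compute_percentiles([0.3] * 10)
        assert all(v == pytest.approx(0.3) for v in pct.values())

    def test_large_normal_sample_median(self):
        rng = np.random.default_rng(9)
        pct = compute_percentiles(rng.normal(0.295, 0.104, 100_000))
        assert pct[50.0] == pytest.approx(0.295, abs=0.003)

    @given(
        data=st.lists(st.floats(-100, 100), min_size=2, max_size=50),
        a=st.floats(0.1, 5.0),
        b=st.floats(-10, 10),
    )
    @settings(max_examples=50, deadline=None)
    def test_monotone_and_affine_equivariant(self, data, a, b):
        pct = compute_percentiles(data)
        vals = list(pct.values())
        assert all(x <= y + 1e-9 for x, y in zip(vals, vals[1:]))
        pct_t = compute_percentiles([a * x + b for x in data])
        for lv in pct:
            assert pct_t[lv] == pytest.approx(a * pct[lv] + b, rel=1e-6, abs=1e-6)

    def test_empty_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            compute_percentiles([])
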