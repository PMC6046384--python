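import numpy as np
import pandas as pd
import pytest

from hrvcc.cohort_stats import (
    bonferroni_alpha,
    cohens_d,
    compare_groups,
    hierarchical_regression,
    hr_adjust,
    normality_screen,
    regression_table,
)
from hrvcc.synthetic import CohortSpec, gen_cohort


@pytest.fixture
def cohort():
    return gen_cohort(CohortSpec(seed=42, missing_rate=0.0))


class TestHRAdjust:
    def test_negatively_correlated_measure_divided(self, cohort):
        adjusted, report = hr_adjust(cohort, measures=["rmssd_ms"])
        assert report.correlations["rmssd_ms"] < 0
        assert report.operations["rmssd_ms"] == "divided_by_hr"
        expected = cohort["rmssd_ms"] / cohort["hr_bpm"]
        assert np.allclose(adjusted["rmssd_ms_adj"], expected)

    def test_positively_correlated_measure_multiplied(self, cohort):
        adjusted, report = hr_adjust(cohort, measures=["dfa_alpha1"])
        assert report.correlations["dfa_alpha1"] > 0
        assert report.operations["dfa_alpha1"] == "multiplied_by_hr"
        expected = cohort["dfa_alpha1"] * cohort["hr_bpm"]
        assert np.allclose(adjusted["dfa_alpha1_adj"], expected)

    def test_zero_variance_measure_left_unadjusted(self, cohort):
        df = cohort.copy()
        df["flat"] = 1.0
        with pytest.warns(UserWarning, match="zero variance"):
            adjusted, report = hr_adjust(df, measures=["flat"])
        assert report.operations["flat"] == "unadjusted"
        assert "flat_adj" not in adjusted

    def test_raw_values_retained(self, cohort):
        adjusted, _ = hr_adjust(cohort)
        for col in ("rmssd_ms", "ln_hf", "fd"):
            assert np.array_equal(adjusted[col], cohort[col])


class TestCohensD:
    def test_symmetry_and_scale_invariance(self):
        d1 = cohens_d(10, 2, 30, 12, 3, 40)
        d2 = cohens_d(12, 3, 40, 10, 2, 30)
        d3 = cohens_d(100, 20, 30, 120, 30, 40)
        assert d1 == pytest.approx(d2) == pytest.approx(d3)

    def test_equal_means_zero(self):
        assert cohens_d(5, 1, 10, 5, 2, 10) == 0.0

    def test_zero_pooled_sd_errors(self):
        with pytest.raises(ValueError, match="pooled SD"):
            cohens_d(1, 0, 10, 2, 0, 10)


class TestCompareGroups:
    def test_f_equals_t_squared(self, cohort):
        from scipy import stats

        res = compare_groups(cohort, ["rmssd_ms", "ln_hf", "fd"])
        boys = cohort[cohort.sex_code == 1]
        girls = cohort[cohort.sex_code == 2]
        for _, row in res.iterrows():
            t, _ = stats.ttest_ind(boys[row.measure], girls[row.measure], equal_var=True)
            assert row.F == pytest.approx(t**2, rel=1e-9)

    def test_identical_groups_f_and_d_zero(self, rng):
        x = rng.normal(50, 5, 40)
        df = pd.DataFrame(
            {"sex_code": [1] * 40 + [2] * 40, "m": np.concatenate([x, x])}
        )
        res = compare_groups(df, ["m"])
        assert res.F.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert res.cohens_d.iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_true_difference_recovered(self, rng):
        # groups half a pooled SD apart at n=80/86: mean estimated d ~ 0.5
        ds = []
        for _ in range(200):
            a = rng.normal(0.0, 1.0, 80)
            b = rng.normal(0.5, 1.0, 86)
            df = pd.DataFrame(
                {"sex_code": [1] * 80 + [2] * 86, "m": np.concatenate([a, b])}
            )
            ds.append(compare_groups(df, ["m"]).cohens_d.iloc[0])
        assert np.mean(ds) == pytest.approx(0.5, abs=0.05)

    def test_single_group_errors(self, cohort):
        only_girls = cohort[cohort.sex_code == 2]
        with pytest.raises(ValueError, match="2 groups"):
            compare_groups(only_girls, ["rmssd_ms"])


class TestBonferroni:
    @pytest.mark.parametrize(
        "family_size,expected", [(2, 0.025), (3, 0.0167), (5, 0.01)]
    )
    def test_family_thresholds(self, family_size, expected):
        assert bonferroni_alpha(0.05, family_size) == pytest.approx(expected, abs=5e-4)

    def test_invalid_family_size(self):
        with pytest.raises(ValueError):
            bonferroni_alpha(0.05, 0)


class TestHierarchicalRegression:
    def test_pure_sex_effect_recovered(self, rng):
        n = 400
        sex = rng.choice([1.0, 2.0], n)
        measure = rng.standard_normal(n)
        y = 2.0 * sex + rng.standard_normal(n)
        df = pd.DataFrame({"sex_code": sex, "m": measure, "y": y})
        r = hierarchical_regression(df, "y", "m")
        assert r.step1.pvalues["sex_code"] < 0.001
        assert abs(r.step1.beta["m"]) < 0.1
        assert r.step1.beta["sex_code"] > 0.5

    def test_true_interaction_raises_step2_delta_r2(self, rng):
        n = 300
        sex = rng.choice([1.0, 2.0], n)
        z = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        with_int = pd.DataFrame(
            {"sex_code": sex, "m": z, "y": 1.5 * sex * z + noise}
        )
        without = pd.DataFrame({"sex_code": sex, "m": z, "y": noise})
        r_with = hierarchical_regression(with_int, "y", "m")
        r_without = hierarchical_regression(without, "y", "m")
        assert r_with.step2.delta_r2 > r_without.step2.delta_r2
        assert r_with.step2.pvalues["sex_code_x_m"] < 1e-6

    def test_standardized_betas_scale_invariant(self, cohort):
        r1 = hierarchical_regression(cohort, "depression", "ln_hf")
        scaled = cohort.copy()
        scaled["ln_hf"] = scaled["ln_hf"] * 1000.0
        r2 = hierarchical_regression(scaled, "depression", "ln_hf")
        assert r1.step1.beta["ln_hf"] == pytest.approx(r2.step1.beta["ln_hf"], rel=1e-9)
        assert r1.step1.beta["sex_code"] == pytest.approx(
            r2.step1.beta["sex_code"], rel=1e-9
        )
        assert r1.step2.delta_r2 == pytest.approx(r2.step2.delta_r2, rel=1e-9)

    def test_r2_cumulative_and_delta_nonnegative(self, cohort):
        r = hierarchical_regression(cohort, "total_anxiety", "hr_bpm")
        assert r.step2.r2 >= r.step1.r2 - 1e-12
        assert r.step2.delta_r2 >= -1e-12

    def test_rank_deficiency_names_columns(self, rng):
        n = 50
        df = pd.DataFrame(
            {"sex_code": np.ones(n), "m": rng.standard_normal(n), "y": rng.standard_normal(n)}
        )
        with pytest.raises(ValueError, match="sex_code"):
            hierarchical_regression(df, "y", "m")

    def test_listwise_deletion(self):
        df = gen_cohort(CohortSpec(seed=3, missing_rate=0.1))
        r = hierarchical_regression(df, "depression", "ln_hf")
        assert r.n == df[["depression", "ln_hf", "sex_code"]].dropna().shape[0]
        assert r.n < len(df)


def test_regression_table_shape(cohort):
    tbl = regression_table(cohort, ["depression", "panic"], ["hr_bpm", "ln_hf"])
    assert len(tbl) == 4
    assert {"beta_sex", "beta_measure", "beta_interaction", "step2_delta_r2"} <= set(
        tbl.columns
    )


def test_normality_screen_flags_lognormal(rng):
    skewed = rng.lognormal(6, 0.8, 200)
    screen = normality_screen(skewed)
    assert screen["p"] < 0.001 and screen["skewness"] > 1
    log_screen = normality_screen(np.log(skewed))
    assert abs(log_screen["skewness"]) < abs(screen["skewness"])
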