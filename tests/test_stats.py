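"""Mixed-effects regressions, ROC/AUC and sensitivity/specificity oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from fundusavr.cohort import CohortSpec, generate_cohort, generate_two_group_cohort
from fundusavr.errors import SchemaError
from fundusavr.stats import (compare_group_means, compare_slopes,
                             fit_mixed_model, roc_analysis, sens_spec_at,
                             validate_observation_table)


def _table(patients, icps, avs):
    return pd.DataFrame({"patient_id": patients, "mean_icp_mmHg": icps,
                         "median_av": avs})


WORKED = _table(["a"] * 4 + ["b"] * 4,
                [25, 26, 27, 28, 15, 16, 17, 18],
                [0.70, 0.75, 0.79, 0.85, 0.78, 0.82, 0.88, 0.90])


def brute_force_auc(diseased, healthy):
    """Pairwise Wilcoxon-Mann-Whitney count: wins + half-ties over all pairs."""
    wins = sum(1.0 if d < h else (0.5 if d == h else 0.0)
               for d, h in itertools.product(diseased, healthy))
    return wins / (len(diseased) * len(healthy))


class TestSchema:
    def test_missing_column_named(self):
        with pytest.raises(SchemaError, match="patient_id"):
            validate_observation_table(pd.DataFrame({"mean_icp_mmHg": [1],
                                                     "median_av": [0.8]}))

    def test_non_finite_value_locates_row(self):
        df = _table(["a", "a"], [10.0, np.nan], [0.8, 0.8])
        with pytest.raises(SchemaError, match="row 1"):
            validate_observation_table(df)

    def test_nonpositive_ratio_rejected(self):
        df = _table(["a", "b"], [10.0, 11.0], [0.8, 0.0])
        with pytest.raises(SchemaError, match="median_av"):
            validate_observation_table(df)

    def test_alias_column_accepted(self):
        df = pd.DataFrame({"patient_id": ["a"], "mean_icp": [10.0],
                           "median_av": [0.8]})
        out = validate_observation_table(df)
        assert "mean_icp_mmHg" in out.columns and "epoch" in out.columns


class TestMixedModel:
    def test_parallel_noiseless_lines_recover_slope_exactly(self):
        rows = [(p, icp, b + 0.002 * icp)
                for p, b in (("p1", 0.80), ("p2", 0.90))
                for icp in (5.0, 8.0, 11.0, 14.0)]
        df = _table(*zip(*rows))
        fit = fit_mixed_model(df)
        assert fit.slope == pytest.approx(0.002, abs=1e-9)
        assert fit.sd_residual == pytest.approx(0.0, abs=1e-3)
        assert fit.slope_ci95[0] <= fit.slope <= fit.slope_ci95[1]

    def test_single_patient_is_rejected(self):
        df = _table(["a"] * 4, [5, 8, 11, 14], [0.8, 0.81, 0.82, 0.83])
        with pytest.raises(SchemaError, match="2 patients"):
            fit_mixed_model(df)

    def test_matches_ols_when_no_patient_heterogeneity(self):
        # identical intercepts, no noise: mixed slope == OLS slope
        spec = CohortSpec(n_patients=3, obs_per_patient=6, icp_range=(16, 28),
                          slope_low=-0.0023, slope_high=-0.0023,
                          sd_random_intercept=0.0, sd_residual=0.0, seed=1)
        df, _ = generate_cohort(spec)
        fit = fit_mixed_model(df)
        ols = np.polyfit(df["mean_icp_mmHg"], df["median_av"], 1)[0]
        assert fit.slope == pytest.approx(ols, abs=1e-6)

    def test_icp_filter_restricts_rows(self):
        df, _ = generate_cohort(CohortSpec(seed=3))
        fit_low = fit_mixed_model(df, lambda icp: icp < 15)
        assert fit_low.n_obs == int((df["mean_icp_mmHg"] < 15).sum())

    def test_slope_recovery_on_synthetic_cohorts(self):
        slopes = []
        for s in range(1, 31):
            df, _ = generate_cohort(CohortSpec(
                n_patients=9, obs_per_patient=5.0, icp_range=(15, 30),
                slope_low=-0.0023, slope_high=-0.0023, seed=s))
            slopes.append(fit_mixed_model(df).slope)
        assert np.mean(slopes) == pytest.approx(-0.0023, abs=6e-4)


class TestCompareSlopes:
    def test_sign_of_delta_matches_generating_slopes(self):
        df, _ = generate_cohort(CohortSpec(sd_random_intercept=0.0,
                                           sd_residual=0.0, seed=2))
        r = compare_slopes(df)
        assert np.sign(r.delta_slope) == np.sign(-0.0023 - 0.0017)
        assert r.slope_low == pytest.approx(0.0017, abs=1e-6)
        assert r.slope_high == pytest.approx(-0.0023, abs=1e-6)

    def test_one_sided_table_rejected(self):
        df, _ = generate_cohort(CohortSpec(icp_range=(16, 28), seed=1))
        with pytest.raises(SchemaError, match="split"):
            compare_slopes(df)

    def test_detects_the_published_slope_difference(self):
        hits = 0
        for s in range(1, 41):
            df, _ = generate_cohort(CohortSpec(seed=s))
            hits += compare_slopes(df).p_interaction < 0.05
        assert hits / 40 >= 0.5  # power at study-sized cohorts


class TestCompareGroupMeans:
    def test_identical_groups(self):
        df = _table(["a", "a", "b", "b"], [16, 22, 17, 23], [0.85] * 4)
        r = compare_group_means(df)
        assert r.mean_low_group == pytest.approx(r.mean_high_group, abs=1e-9)
        assert r.p > 0.9

    def test_noiseless_shift_recovered_exactly(self):
        df, _ = generate_two_group_cohort(mean_low=0.88, mean_high=0.86,
                                          sd_random_intercept=0.0,
                                          sd_residual=0.0, seed=3)
        r = compare_group_means(df)
        assert r.mean_high_group - r.mean_low_group == pytest.approx(-0.02, abs=1e-9)

    def test_empty_group_rejected(self):
        df = _table(["a", "b"], [16.0, 17.0], [0.85, 0.86])
        with pytest.raises(SchemaError, match="boundary"):
            compare_group_means(df)


class TestROC:
    def test_perfect_and_null_separation(self):
        perfect = _table(["a"] * 3 + ["b"] * 3, [25, 26, 27, 15, 16, 17],
                         [0.6, 0.65, 0.7, 0.8, 0.85, 0.9])
        assert roc_analysis(perfect, n_bootstrap=10).auc == 1.0
        null = _table(["a"] * 3 + ["b"] * 3, [25, 26, 27, 15, 16, 17],
                      [0.8, 0.8, 0.8, 0.8, 0.8, 0.8])
        assert roc_analysis(null, n_bootstrap=10).auc == 0.5

    def test_worked_example_matches_pairwise_oracle(self):
        d = WORKED.loc[WORKED["mean_icp_mmHg"] >= 20, "median_av"]
        h = WORKED.loc[WORKED["mean_icp_mmHg"] < 20, "median_av"]
        oracle = brute_force_auc(d.to_numpy(), h.to_numpy())
        result = roc_analysis(WORKED, n_bootstrap=50, seed=1)
        assert oracle == pytest.approx(13 / 16)
        assert result.auc == pytest.approx(oracle, abs=1e-12)

    def test_auc_equals_wilcoxon_statistic_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n_d, n_h = rng.integers(2, 15, size=2)
            d = rng.uniform(0.6, 1.0, n_d).round(2)
            h = rng.uniform(0.6, 1.0, n_h).round(2)  # rounding forces ties
            df = _table(["a"] * n_d + ["b"] * n_h,
                        [25] * n_d + [15] * n_h, np.concatenate([d, h]))
            r = roc_analysis(df, n_bootstrap=2, seed=0)
            assert r.auc == pytest.approx(brute_force_auc(d, h), abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score
        df, _ = generate_two_group_cohort(seed=9)
        r = roc_analysis(df, n_bootstrap=2, seed=0)
        y = (df["mean_icp_mmHg"] >= 20).astype(int)
        assert r.auc == pytest.approx(roc_auc_score(y, -df["median_av"]), abs=1e-12)

    def test_bootstrap_ci_is_seeded_and_ordered(self):
        df, _ = generate_two_group_cohort(seed=4)
        a = roc_analysis(df, n_bootstrap=200, seed=7)
        b = roc_analysis(df, n_bootstrap=200, seed=7)
        assert a.auc_ci95 == b.auc_ci95
        assert a.auc_ci95[0] <= a.auc <= a.auc_ci95[1]

    def test_single_class_rejected(self):
        df = _table(["a", "b"], [25.0, 26.0], [0.7, 0.75])
        with pytest.raises(SchemaError, match="both classes"):
            roc_analysis(df, n_bootstrap=2)


class TestSensSpec:
    def test_worked_example_counts(self):
        r = sens_spec_at(WORKED, cutoff=0.8015)
        assert r.sensitivity == pytest.approx(0.75)
        assert r.specificity == pytest.approx(0.75)
        assert r.lr_positive == pytest.approx(3.0)
        assert r.sensitivity_ci95[0] < 0.75 < r.sensitivity_ci95[1]

    def test_extreme_cutoffs(self):
        perfect = _table(["a"] * 3 + ["b"] * 3, [25, 26, 27, 15, 16, 17],
                         [0.6, 0.65, 0.7, 0.8, 0.85, 0.9])
        r = sens_spec_at(perfect, cutoff=0.75)
        assert r.sensitivity == 1.0 and r.specificity == 1.0
        r0 = sens_spec_at(perfect, cutoff=0.5)
        assert r0.sensitivity == 0.0 and r0.specificity == 1.0
        assert np.isnan(r0.lr_positive)  # 0/0: no positives at all

    def test_matches_roc_curve_point_at_same_threshold(self):
        df, _ = generate_two_group_cohort(seed=5)
        r = roc_analysis(df, n_bootstrap=2, seed=0)
        for t, sens, spec in r.curve[1:-1]:
            ss = sens_spec_at(df, cutoff=t)
            assert ss.sensitivity == pytest.approx(sens, abs=1e-12)
            assert ss.specificity == pytest.approx(spec, abs=1e-12)

    def test_lr_identity_holds(self):
        df, _ = generate_two_group_cohort(seed=6)
        r = sens_spec_at(df)
        if r.specificity < 1.0:
            assert r.lr_positive == pytest.approx(
                r.sensitivity / (1 - r.specificity))
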