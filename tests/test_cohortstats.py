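"""Exclusion filtering, association models, and survival statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tsrquant.cohortstats import (
    apply_exclusions,
    baseline_compare,
    cox_model,
    km_estimate,
    logistic_association,
    logrank_test,
    stratified_tsr_analysis,
)
from tsrquant.labels import HIGH_STROMAL, LOW_STROMAL
from tsrquant.synthdata import (
    CohortSpec,
    default_cohort_spec,
    generate_cohort,
    generate_exclusion_roster,
)


class TestApplyExclusions:
    def test_study_roster_filters_to_included(self):
        roster = generate_exclusion_roster(400, (20, 4, 4, 8, 4), seed=1)
        included, counts = apply_exclusions(roster)
        assert len(included) == 400
        assert sum(counts.values()) == 40
        assert counts["metastasis_or_r2"] == 20 and counts["lost_to_followup"] == 4

    def test_no_flags_is_identity(self):
        roster = generate_exclusion_roster(25, (0, 0, 0, 0, 0))
        included, counts = apply_exclusions(roster)
        assert included.equals(roster)
        assert all(v == 0 for v in counts.values())

    def test_multiflag_patient_counted_once_at_higher_priority(self):
        roster = generate_exclusion_roster(2, (0, 0, 0, 0, 0))
        roster.loc[0, ["neoadjuvant", "death_within_90d"]] = True
        included, counts = apply_exclusions(roster)
        assert len(included) == 1
        assert counts["neoadjuvant"] == 1 and counts["death_within_90d"] == 0

    def test_missing_flag_column_rejected(self):
        with pytest.raises(KeyError):
            apply_exclusions(pd.DataFrame({"patient_id": ["P1"]}))


class TestBaselineCompare:
    def test_identical_distributions_give_null_statistic(self):
        cohort = pd.DataFrame(
            {"grp": ["a"] * 40 + ["b"] * 40, "var": ([0] * 25 + [1] * 15) * 2}
        )
        res = baseline_compare(cohort, "grp", "var")
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_chi2_matches_conditional_permutation_oracle(self):
        # A published-style age split across two cohorts: 132/75 vs 125/68.
        cohort = pd.DataFrame(
            {
                "cohort": ["dev"] * 207 + ["val"] * 193,
                "age_le_65": [1] * 132 + [0] * 75 + [1] * 125 + [0] * 68,
            }
        )
        res = baseline_compare(cohort, "cohort", "age_le_65")
        assert res.test == "chi2"
        assert res.p_value == pytest.approx(0.835, abs=0.02)
        # Oracle: conditional (fixed-margin) Monte-Carlo null of the statistic.
        rng = np.random.default_rng(0)
        n, row1, col1 = 400, 207, 257
        a_obs = 132

        def chi2_of_a(a):
            table = np.array(
                [[a, row1 - a], [col1 - a, n - row1 - col1 + a]], dtype=float
            )
            exp = np.outer(table.sum(1), table.sum(0)) / n
            return ((table - exp) ** 2 / exp).sum()

        draws = rng.hypergeometric(col1, n - col1, row1, size=4000)
        stat_null = np.array([chi2_of_a(a) for a in draws])
        obs = chi2_of_a(a_obs)
        # Mid-p corrects for the discreteness of the conditional null, which
        # is non-negligible for near-zero statistics like this one.
        p_perm = (stat_null > obs + 1e-12).mean() + 0.5 * (
            np.abs(stat_null - obs) <= 1e-12
        ).mean()
        assert abs(res.p_value - p_perm) < 0.05

    def test_separated_groups_give_tiny_p(self):
        cohort = pd.DataFrame(
            {"grp": ["a"] * 50 + ["b"] * 50, "var": [0] * 50 + [1] * 50}
        )
        assert baseline_compare(cohort, "grp", "var").p_value < 1e-10

    def test_continuous_variable_uses_ranksum(self):
        rng = np.random.default_rng(1)
        cohort = pd.DataFrame(
            {"grp": ["a"] * 60 + ["b"] * 60, "var": rng.normal(size=120)}
        )
        assert baseline_compare(cohort, "grp", "var").test == "ranksum"

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            baseline_compare(pd.DataFrame({"g": ["a"] * 5, "v": range(5)}), "g", "v")


class TestLogisticAssociation:
    def test_single_covariate_univariate_equals_multivariate(self):
        cohort = generate_cohort(
            CohortSpec(
                n=800, binary_covariates={"necrosis": 0.5},
                logistic_effects={"necrosis": math.log(3.5)},
                logistic_intercept=-0.5, seed=2,
            )
        )
        res = logistic_association(cohort, ["necrosis"])
        assert res.univariate[0].estimate == pytest.approx(res.multivariate[0].estimate)

    def test_null_effects_cis_cover_zero(self):
        covered = 0
        n_runs = 100  # enough runs that Monte-Carlo noise cannot mask 95% coverage
        for seed in range(n_runs):
            cohort = generate_cohort(
                CohortSpec(
                    n=1000, binary_covariates={"x": 0.5},
                    logistic_effects={"x": 0.0}, seed=300 + seed,
                )
            )
            res = logistic_association(cohort, ["x"], entry_p=1.1)
            r = res.multivariate[0]
            covered += r.ci_low <= 1.0 <= r.ci_high  # OR scale: covers 1
        assert covered >= 0.90 * n_runs

    def test_or_recovery_matches_generative_truth(self):
        estimates = []
        for seed in range(5):
            cohort = generate_cohort(
                CohortSpec(
                    n=4000, binary_covariates={"necrosis": 0.5, "r1": 0.35},
                    logistic_effects={"necrosis": math.log(3.53), "r1": math.log(2.281)},
                    logistic_intercept=-0.6, seed=40 + seed,
                )
            )
            res = logistic_association(cohort, ["necrosis", "r1"])
            estimates.append(dict((r.term, r.ratio) for r in res.multivariate)["necrosis"])
        assert 3.0 <= np.mean(estimates) <= 4.1

    def test_no_survivor_returns_univariate_with_warning(self):
        cohort = generate_cohort(
            CohortSpec(n=300, binary_covariates={"x": 0.5},
                       logistic_effects={"x": 0.0}, seed=7)
        )
        res = logistic_association(cohort, ["x"], entry_p=1e-6)
        assert res.multivariate == () and res.warning is not None


class TestCoxModel:
    def test_duplicate_covariate_enters_once(self):
        cohort = generate_cohort(
            CohortSpec(n=600, binary_covariates={"x": 0.5},
                       log_hazard_effects={"x": 0.9}, seed=3)
        )
        cohort["x_copy"] = cohort["x"]
        res = cox_model(cohort, ["x", "x_copy"])
        assert res.selected == ("x",)  # tie broken by candidate order

    def test_forward_selection_keeps_true_effects(self):
        spec = default_cohort_spec(n=1500, seed=5)
        cohort = generate_cohort(spec)
        res = cox_model(
            cohort,
            ["tnm_stage_II", "tnm_stage_III", "low_stromal", "grade_g3",
             "perineural_invasion", "lymphovascular_invasion"],
        )
        assert "tnm_stage_III" in res.selected  # strongest generative effect
        assert set(res.selected) <= set(res.screened)
        for r in res.multivariate:
            assert r.ci_low <= r.ratio <= r.ci_high
            assert r.ratio == pytest.approx(math.exp(r.estimate))

    def test_no_event_cohort_rejected(self):
        cohort = pd.DataFrame({"os_months": [1.0, 2.0], "event": [0, 0], "x": [0, 1]})
        with pytest.raises(ValueError):
            cox_model(cohort, ["x"])

    def test_nothing_passes_screen_warns(self):
        cohort = generate_cohort(
            CohortSpec(n=200, binary_covariates={"x": 0.5}, seed=11)
        )
        res = cox_model(cohort, ["x"], screen_p=1e-9)
        assert res.multivariate == () and "screen" in res.warning


class TestKaplanMeier:
    def test_hand_product_limit_calculation(self):
        curve = km_estimate([1, 2, 3], [1, 1, 0])
        np.testing.assert_allclose(curve.times, [1, 2, 3])
        np.testing.assert_allclose(curve.survival, [2 / 3, 1 / 3, 1 / 3])
        np.testing.assert_allclose(curve.at_risk, [3, 2, 1])

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(10, size=200)
        curve = km_estimate(times, np.ones(200, dtype=int))
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx((times > t).mean(), abs=1e-12)

    def test_all_censored_flat_at_one(self):
        curve = km_estimate([3, 5, 8], [0, 0, 0])
        np.testing.assert_allclose(curve.survival, 1.0)
        np.testing.assert_allclose(curve.variance, 0.0)

    def test_curve_monotone_bounded_with_greenwood_variance(self):
        rng = np.random.default_rng(6)
        times = rng.exponential(10, size=150)
        events = rng.random(150) < 0.7
        curve = km_estimate(times, events.astype(int))
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert ((curve.survival >= 0) & (curve.survival <= 1)).all()
        assert (np.diff(curve.at_risk) < 0).all()
        assert (curve.variance >= 0).all()

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([-1, 2], [1, 1])


class TestLogrank:
    def test_identical_groups_null(self):
        t = list(range(1, 31))
        e = [1] * 30
        res = logrank_test([t, t], [e, e])
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == pytest.approx(1.0)

    def test_power_under_strong_effect(self):
        # HR = 4 between arms of 200: essentially always detected.
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(500 + seed)
            t0 = rng.exponential(1 / 0.02, size=200)
            t1 = rng.exponential(1 / 0.08, size=200)
            res = logrank_test([t0, t1], [np.ones(200)] * 2)
            hits += res.p_value < 0.001
        assert hits >= 19  # >= 95% of runs

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([[1, 2], []], [[1, 1], []])


class TestStratifiedTSR:
    def test_high_stromal_curves_dominate_each_stage(self):
        cohort = generate_cohort(default_cohort_spec(n=3000, seed=8))
        strata = stratified_tsr_analysis(cohort)
        assert set(strata) == {"I", "II", "III"}
        for res in strata.values():
            t_med = np.median(cohort.os_months)
            s_high = res.curves[HIGH_STROMAL].step_function(t_med)
            s_low = res.curves[LOW_STROMAL].step_function(t_med)
            assert s_high > s_low  # better survival with high stroma

    def test_shuffled_categories_match_null_rejection_rate(self):
        cohort = generate_cohort(default_cohort_spec(n=400, seed=9))
        rng = np.random.default_rng(9)
        pvals = []
        for _ in range(20):
            shuffled = cohort.copy()
            shuffled["tsr_category"] = rng.permutation(cohort.tsr_category.to_numpy())
            for res in stratified_tsr_analysis(shuffled).values():
                pvals.append(res.logrank.p_value)
        # Per-stratum null: about 5% of log-rank tests significant.
        assert np.mean(np.array(pvals) > 0.05) >= 0.90

    def test_single_category_stratum_skipped_with_warning(self):
        cohort = generate_cohort(default_cohort_spec(n=300, seed=10))
        cohort.loc[cohort.tnm_stage == "I", "tsr_category"] = HIGH_STROMAL
        with pytest.warns(RuntimeWarning, match="single TSR category"):
            strata = stratified_tsr_analysis(cohort)
        assert "I" not in strata and {"II", "III"} <= set(strata)

    def test_single_stage_cohort_gives_one_panel(self):
        cohort = generate_cohort(default_cohort_spec(n=300, seed=12))
        sub = cohort[cohort.tnm_stage == "II"].reset_index(drop=True)
        assert list(stratified_tsr_analysis(sub)) == ["II"]
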