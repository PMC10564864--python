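"""Screening, imputation, model fitting, pooling, AIC selection, recovery."""

import numpy as np
import pandas as pd
import pytest

from glycoquant.association import (
    ImputationSet,
    ModelFitError,
    ModelSpec,
    _select_rule,
    fit_binary_model,
    fit_cox_model,
    impute_chained,
    run_analysis,
    run_recovery,
    run_stratified,
    screen_confounders,
    select_by_aic,
)
from glycoquant.cohort import CohortGenerator, GeneratorConfig, inject_missingness


class TestScreening:
    def test_double_rule_at_boundary(self):
        assert _select_rule(0.09, 0.11, 0.1) is False
        assert _select_rule(0.09, 0.09, 0.1) is True
        assert _select_rule(0.1, 0.05, 0.1) is False

    def test_true_common_cause_selected(self, cohort_study_size):
        # age both shifts the exposure and enters the outcome model
        res = screen_confounders(cohort_study_size, "iph", ["age"])
        assert res[0].selected

    def test_null_candidate_rarely_selected(self):
        rng = np.random.default_rng(0)
        n, hits, reps = 500, 0, 300
        for _ in range(reps):
            df = pd.DataFrame(
                {
                    "glyc_sd": rng.standard_normal(n),
                    "plaque_sd": rng.standard_normal(n),
                    "iph": rng.integers(0, 2, n),
                    "noise": rng.standard_normal(n),
                }
            )
            hits += screen_confounders(df, "iph", ["noise"])[0].selected
        # independent double rule: selection probability ≈ 0.1 × 0.1
        assert hits / reps <= 0.04

    def test_constant_candidate_excluded_with_warning(self, cohort_study_size, caplog):
        df = cohort_study_size.assign(constant=1.0)
        with caplog.at_level("WARNING"):
            res = screen_confounders(df, "iph", ["constant"])
        assert res == []
        assert "constant" in caplog.text

    def test_exposure_and_outcome_not_allowed_as_candidates(self, cohort_study_size):
        with pytest.raises(ValueError):
            screen_confounders(cohort_study_size, "iph", ["glyc_sd"])


class TestImputation:
    def test_no_missing_returns_identical_copies(self, cohort_study_size):
        out = impute_chained(cohort_study_size, m=3, seed=1)
        assert out.m == 3
        for t in out.completed_tables:
            pd.testing.assert_frame_equal(t, cohort_study_size)

    def test_observed_cells_identical_across_copies(self, cohort_study_size):
        masked = inject_missingness(cohort_study_size, {"egfr": 0.1, "smoking": 0.1}, seed=2)
        out = impute_chained(masked, m=3, iterations=5, seed=2)
        obs = ~masked["egfr"].isna()
        for t in out.completed_tables:
            assert not t.isna().any().any()
            assert (t.loc[obs, "egfr"] == masked.loc[obs, "egfr"]).all()
        # chains use distinct streams: imputed values differ between copies
        miss = masked["egfr"].isna()
        assert not (
            out.completed_tables[0].loc[miss, "egfr"]
            == out.completed_tables[1].loc[miss, "egfr"]
        ).all()

    def test_imputed_categoricals_take_observed_levels(self, cohort_study_size):
        masked = inject_missingness(cohort_study_size, {"smoking": 0.2}, seed=3)
        out = impute_chained(masked, m=2, iterations=5, seed=3)
        assert set(out.completed_tables[0]["smoking"]) <= {"current", "ex", "never"}

    def test_over_half_missing_rejected(self, cohort_study_size):
        df = cohort_study_size.copy()
        df.loc[df.index[: int(0.6 * len(df))], "bmi"] = np.nan
        with pytest.raises(ValueError):
            impute_chained(df, m=2, seed=1)

    def test_mcar_pooled_estimate_near_complete_data(self, calibrated_generator):
        diffs = []
        for s in range(10):
            df = calibrated_generator.generate(1000 + s)
            full = fit_binary_model(ModelSpec(outcome="iph"), df).term("glyc_sd")["estimate"]
            masked = inject_missingness(df, {"egfr": 0.1}, seed=s)
            imp = impute_chained(masked, m=5, iterations=5, seed=s)
            pooled = fit_binary_model(ModelSpec(outcome="iph"), imp).term("glyc_sd")["estimate"]
            diffs.append(pooled - full)
        assert abs(np.mean(diffs)) < 0.05


class TestModelFits:
    def test_model1_contains_plaque_size_term(self, cohort_study_size):
        res = fit_binary_model(
            ModelSpec(outcome="iph", model_tier="model1"), cohort_study_size
        )
        assert "plaque_sd" in res.terms.index
        assert res.family == "logistic"

    def test_ratio_is_exp_of_estimate_with_bracketing_ci(self, cohort_study_size):
        res = fit_binary_model(ModelSpec(outcome="iph"), cohort_study_size)
        for _, row in res.terms.iterrows():
            assert row["ratio"] == pytest.approx(np.exp(row["estimate"]), rel=1e-9)
            assert row["ci_low"] <= row["ratio"] <= row["ci_high"]

    def test_pooling_complete_copies_equals_single_fit(self, cohort_study_size):
        single = fit_binary_model(ModelSpec(outcome="iph"), cohort_study_size)
        imp = ImputationSet(3, [cohort_study_size.copy() for _ in range(3)], 0, 0)
        pooled = fit_binary_model(ModelSpec(outcome="iph"), imp)
        assert pooled.pooled
        assert np.allclose(pooled.terms["estimate"], single.terms["estimate"])
        assert np.allclose(pooled.terms["se"], single.terms["se"], rtol=1e-6)

    def test_complete_separation_raises(self):
        rng = np.random.default_rng(1)
        n = 200
        x = rng.standard_normal(n)
        df = pd.DataFrame(
            {
                "glyc_sd": x,
                "plaque_sd": rng.standard_normal(n),
                "iph": (x > 0).astype(int),
            }
        )
        with pytest.raises(ModelFitError):
            fit_binary_model(ModelSpec(outcome="iph", model_tier="model1"), df)

    def test_cox_recovers_null_and_rejects_no_events(self, calibrated_generator):
        cfg = GeneratorConfig(n=4000, hr_mace_per_sd=0.0)
        gen = CohortGenerator(cfg)
        logs = [
            fit_cox_model(ModelSpec(outcome="mace", family="cox"), gen.generate(s))
            .term("glyc_sd")["estimate"]
            for s in range(10)
        ]
        assert abs(np.mean(logs)) < 0.05
        df = calibrated_generator.generate(55).copy()
        df["mace_event"] = 0
        with pytest.raises(ModelFitError):
            fit_cox_model(ModelSpec(outcome="mace", family="cox"), df)


class TestAicSelection:
    def test_intercept_only_aic_matches_closed_form(self):
        # 10 observations, 7 events: lnL = 7 ln 0.7 + 3 ln 0.3, AIC = 2 - 2 lnL
        df = pd.DataFrame(
            {
                "glyc_sd": np.zeros(10),
                "plaque_sd": np.zeros(10),
                "y": [1] * 7 + [0] * 3,
            }
        )
        import statsmodels.api as sm

        res = sm.Logit(df["y"], np.ones((10, 1))).fit(disp=0)
        expected = 2.0 - 2.0 * (7 * np.log(0.7) + 3 * np.log(0.3))
        assert res.aic == pytest.approx(expected, rel=1e-9)

    def test_argmin_and_shared_outcome_contract(self, cohort_study_size):
        m1 = ModelSpec(outcome="iph", model_tier="model1")
        m2 = ModelSpec(outcome="iph", model_tier="model2")
        best, table = select_by_aic([m1, m2], cohort_study_size)
        assert best.model_tier == table.sort_values(["aic", "n_params"]).iloc[0]["model_tier"]
        with pytest.raises(ValueError):
            select_by_aic([m1, ModelSpec(outcome="symptomatic")], cohort_study_size)

    def test_tie_breaks_to_smaller_model(self, cohort_study_size):
        # a duplicated spec fits identically: the first (equal-size) wins,
        # and adding a redundant constant-free larger spec cannot win a tie
        m1 = ModelSpec(outcome="iph", model_tier="model1")
        best, _ = select_by_aic([m1, m1], cohort_study_size)
        assert best == m1


class TestStratified:
    def test_missing_sex_column_rejected(self, cohort_study_size):
        df = cohort_study_size.drop(columns=["sex"])
        with pytest.raises(ValueError):
            run_stratified(ModelSpec(outcome="iph"), df)

    def test_women_ci_wider_than_men(self, cohort_study_size):
        out = run_stratified(ModelSpec(outcome="iph"), cohort_study_size)
        assert set(out) == {"all", "men", "women"}
        width = {
            k: np.log(v.term("glyc_sd")["ci_high"]) - np.log(v.term("glyc_sd")["ci_low"])
            for k, v in out.items()
        }
        assert width["women"] > width["men"]

    def test_male_only_symptom_effect_shows_sex_difference(self):
        cfg = GeneratorConfig(
            n=1819,
            beta_sympt_male=np.log(1.37),
            beta_sympt_female=np.log(1.15),
        )
        gen = CohortGenerator(cfg)
        male_logs, female_logs = [], []
        for s in range(20):
            out = run_stratified(ModelSpec(outcome="symptomatic"), gen.generate(s))
            male_logs.append(out["men"].term("glyc_sd")["estimate"])
            female_logs.append(out["women"].term("glyc_sd")["estimate"])
        assert np.mean(male_logs) > np.mean(female_logs)
        assert np.mean(male_logs) == pytest.approx(np.log(1.37), abs=0.08)

    def test_small_stratum_warns_but_fits(self, calibrated_generator):
        df = calibrated_generator.generate(77)
        women = df[df["sex"] == "female"].head(60)
        sub = pd.concat([df[df["sex"] == "male"], women.head(45)])
        with pytest.warns(UserWarning, match="stratum"):
            out = run_stratified(ModelSpec(outcome="iph", model_tier="model1"), sub)
        assert out["women"].n_used <= 45


class TestRecovery:
    def test_minimum_replicates_enforced(self, default_config):
        with pytest.raises(ValueError):
            run_recovery(default_config, n_replicates=50)

    def test_iph_effect_recovered(self, default_config):
        rep = run_recovery(
            default_config, outcomes=("iph",), n_replicates=100, seed=314
        )["iph"]
        assert abs(rep.mean_ratio - 1.90) <= 0.1
        assert abs(rep.bias_log) < 0.05
        assert 0.90 <= rep.ci_coverage <= 0.99
        assert rep.n_replicates == 100


class TestRunAnalysis:
    def test_no_candidates_gives_model1_only(self, cohort_study_size):
        table, log = run_analysis(
            cohort_study_size, outcomes=("iph",), candidates=None, stratify=False
        )
        assert set(table["model"]) == {"model1"}
        assert log["screening"] == {}

    def test_screened_model2_present_on_confounded_cohort(self, cohort_study_size):
        table, log = run_analysis(
            cohort_study_size, outcomes=("iph",),
            candidates=("age", "egfr", "statins"), stratify=False,
        )
        assert "model2" in set(table["model"])
        assert log["screening"]["iph"]["age"]["selected"]
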