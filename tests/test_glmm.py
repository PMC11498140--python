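import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy.special import expit

from dispersalshare.glmm import (
    ModelSpec,
    assemble_model_data,
    build_design,
    fit_glmm,
    forward_select,
    likelihood_ratio_test,
    marginal_loglik,
    per_timepoint_models,
    screen_interaction,
    simulate_residuals,
)

from conftest import make_glmm_data


class TestModelSpec:
    def test_interaction_requires_main_effect(self):
        with pytest.raises(ValueError, match="main effect"):
            ModelSpec(terms=(), interactions=("built",))

    def test_interaction_requires_timepoint(self):
        with pytest.raises(ValueError, match="timepoint"):
            ModelSpec(terms=("built",), interactions=("built",), include_timepoint=False)


class TestBuildDesign:
    def test_reference_level_is_spring(self, glmm_data):
        X, names = build_design(glmm_data, ModelSpec(("built",), (), True))
        assert names == ["(Intercept)", "timepointA", "timepointW", "built"]

    def test_interaction_columns(self, glmm_data):
        X, names = build_design(glmm_data, ModelSpec(("built",), ("built",), True))
        assert "built:timepointA" in names and "built:timepointW" in names
        a = glmm_data["timepoint"].to_numpy() == "A"
        j = names.index("built:timepointA")
        assert np.allclose(X[:, j], glmm_data["built"].to_numpy() * a)


class TestFitGlmm:
    def test_intercept_only_half_proportion(self):
        df = pd.DataFrame(
            {
                "subject": ["s1", "s1", "s2", "s2"],
                "timepoint": ["S"] * 4,
                "k": [5, 5, 5, 5],
                "n": [10, 10, 10, 10],
            }
        )
        fit = fit_glmm(ModelSpec((), (), False), df)
        assert fit.estimates[0] == pytest.approx(0.0, abs=1e-4)
        assert fit.random_intercept_sd == pytest.approx(0.0, abs=1e-3)

    def test_glm_limit_matches_statsmodels(self):
        rng = np.random.default_rng(22)
        df = make_glmm_data(rng, n_subjects=50, beta_x=0.6, sigma=0.0)
        fit = fit_glmm(ModelSpec(("built",), (), True), df, fix_sigma=0.0)
        X, _ = build_design(df, ModelSpec(("built",), (), True))
        glm = sm.GLM(
            np.column_stack([df["k"], df["n"] - df["k"]]), X, family=sm.families.Binomial()
        ).fit()
        assert np.max(np.abs(glm.params - fit.estimates)) < 1e-3
        assert fit.loglik == pytest.approx(glm.llf, abs=0.01)

    def test_aic_identity(self, glmm_data):
        fit = fit_glmm(ModelSpec(("built",), (), True), glmm_data)
        assert fit.aic == pytest.approx(
            2 * fit.n_parameters - 2 * fit.loglik, abs=1e-8
        )

    def test_invariant_to_row_order_and_relabeling(self, glmm_data):
        fit1 = fit_glmm(ModelSpec(("built",), (), True), glmm_data)
        shuffled = glmm_data.sample(frac=1.0, random_state=3).reset_index(drop=True)
        shuffled["subject"] = "x" + shuffled["subject"]
        fit2 = fit_glmm(ModelSpec(("built",), (), True), shuffled)
        assert np.allclose(fit1.estimates, fit2.estimates, atol=1e-5)
        assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-5)

    def test_sigma_zero_objective_is_exact_binomial_loglik(self, glmm_data):
        spec = ModelSpec(("built",), (), True)
        X, _ = build_design(glmm_data, spec)
        k = glmm_data["k"].to_numpy(float)
        n = glmm_data["n"].to_numpy(float)
        subjects = list(dict.fromkeys(glmm_data["subject"]))
        groups = np.array([subjects.index(s) for s in glmm_data["subject"]])
        beta = np.array([-1.5, 0.1, 0.4, 0.8])
        ll, _ = marginal_loglik(beta, 0.0, X, k, n, groups, len(subjects))
        eta = X @ beta
        closed = float((k * eta - n * np.log1p(np.exp(eta))).sum())
        assert ll == pytest.approx(closed, abs=1e-10)

    def test_missing_values_rejected(self, glmm_data):
        bad = glmm_data.copy()
        bad.loc[0, "built"] = np.nan
        with pytest.raises(ValueError, match="missing"):
            fit_glmm(ModelSpec(("built",), (), True), bad)

    def test_rank_deficiency_names_terms(self, glmm_data):
        dup = glmm_data.copy()
        dup["built2"] = dup["built"]
        with pytest.raises(ValueError, match="built2"):
            fit_glmm(ModelSpec(("built", "built2"), (), True), dup)

    def test_parameter_recovery_small(self):
        hits = 0
        reps = 20
        for r in range(reps):
            rng = np.random.default_rng(1000 + r)
            df = make_glmm_data(rng, n_subjects=60, beta0=-2.0, beta_x=0.8, sigma=0.5)
            fit = fit_glmm(ModelSpec(("built",), (), True), df)
            est, se, _, _ = fit.coefficients["built"]
            if abs(est - 0.8) <= 2 * se:
                hits += 1
        assert hits >= reps * 0.8

    def test_agq_refines_laplace(self):
        rng = np.random.default_rng(5)
        df = make_glmm_data(rng, n_subjects=30, beta_x=0.5, sigma=0.8, n_range=(5, 15))
        fit1 = fit_glmm(ModelSpec(("built",), (), True), df, nagq=1)
        fit9 = fit_glmm(ModelSpec(("built",), (), True), df, nagq=9)
        # both estimate the same model; small-n binomials differ slightly
        assert np.allclose(fit1.estimates, fit9.estimates, atol=0.05)
        assert abs(fit1.loglik - fit9.loglik) < 0.5


class TestScreenInteraction:
    def test_true_interaction_detected(self):
        rng = np.random.default_rng(31)
        detected = 0
        reps = 12
        for r in range(reps):
            rng_r = np.random.default_rng(400 + r)
            df = make_glmm_data(
                rng_r, n_subjects=40, beta_x=0.3, sigma=0.3, interaction=(0.0, 1.0)
            )
            scr = screen_interaction("built", df)
            detected += scr.keep_interaction
        assert detected >= reps * 0.6

    def test_null_keeps_main_effect_model(self):
        rng = np.random.default_rng(32)
        df = make_glmm_data(rng, n_subjects=40, beta_x=0.0, sigma=0.3)
        scr = screen_interaction("built", df)
        # most of the time no interaction is kept; the chosen model always
        # contains the candidate main effect
        assert "built" in scr.model.coefficient_names

    def test_single_timepoint_degenerate(self):
        rng = np.random.default_rng(33)
        df = make_glmm_data(rng, n_subjects=20, timepoints=("S",))
        with pytest.raises(ValueError, match="degenerate"):
            screen_interaction("built", df)


class TestForwardSelect:
    def test_strong_candidate_selected(self):
        rng = np.random.default_rng(41)
        df = make_glmm_data(rng, n_subjects=40, beta_x=1.5, sigma=0.3)
        fit, trace = forward_select(["built"], df)
        assert trace.selected == ["built"]
        assert trace.steps[0]["kind"] == "p_gate"

    def test_null_usually_not_selected(self):
        rng = np.random.default_rng(42)
        selected = 0
        reps = 20
        for r in range(reps):
            rng_r = np.random.default_rng(800 + r)
            df = make_glmm_data(rng_r, n_subjects=30, beta_x=0.0, sigma=0.3)
            _, trace = forward_select(["built"], df)
            selected += bool(trace.selected)
        assert selected <= 4  # ~5% nominal; allow generous slack at 20 reps

    def test_collinear_duplicate_never_enters(self):
        rng = np.random.default_rng(43)
        df = make_glmm_data(rng, n_subjects=40, beta_x=1.2, sigma=0.3)
        df["outdoor"] = df["built"] + rng.normal(0, 1e-4, len(df))
        fit, trace = forward_select(["built", "outdoor"], df)
        assert trace.selected == ["built"]

    def test_missing_data_protocol(self):
        rng = np.random.default_rng(44)
        df = make_glmm_data(rng, n_subjects=40, beta_x=1.5, sigma=0.3)
        df["outdoor"] = rng.normal(size=len(df))
        # knock out some rows for outdoor only
        df.loc[df.index[:30], "outdoor"] = np.nan
        fit, trace = forward_select(["built", "outdoor"], df)
        step1 = {c["candidate"]: c for c in trace.steps[0]["candidates"]}
        assert step1["built"]["n_rows"] == len(df)
        assert step1["outdoor"]["n_rows"] == len(df) - 30
        # final refit drops rows missing in SELECTED variables only
        final_rows = trace.steps[-1]["n_rows"]
        if trace.selected == ["built"]:
            assert final_rows == len(df)

    def test_marginality_enforced(self):
        rng = np.random.default_rng(45)
        df = make_glmm_data(rng, n_subjects=40, beta_x=0.8, sigma=0.3, interaction=(0.5, 1.0))
        fit, trace = forward_select(["built"], df)
        names = fit.coefficient_names
        for name in names:
            if ":" in name:
                main = name.split(":")[0]
                assert main in names

    def test_empty_candidates_rejected(self, glmm_data):
        with pytest.raises(ValueError):
            forward_select([], glmm_data)

    def test_no_candidate_gives_timepoint_only_model(self):
        rng = np.random.default_rng(46)
        df = make_glmm_data(rng, n_subjects=25, beta_x=0.0, sigma=0.2)
        # make the candidate hopeless by zeroing it out -> rank error caught,
        # selection falls through to the timepoint-only model
        df["built"] = 0.0
        fit, trace = forward_select(["built"], df)
        assert trace.selected == []
        assert fit.coefficient_names == ["(Intercept)", "timepointA", "timepointW"]


class TestPerTimepointModels:
    def test_three_timepoints_three_entries(self):
        rng = np.random.default_rng(51)
        df = make_glmm_data(rng, n_subjects=30, beta_x=1.2, sigma=0.3)
        results, skipped = per_timepoint_models(["built"], df)
        assert set(results) == {"S", "A", "W"}
        assert skipped == {}
        for tp, (fit, _) in results.items():
            assert "timepointA" not in fit.coefficient_names

    def test_small_stratum_skipped(self):
        rng = np.random.default_rng(52)
        df = make_glmm_data(rng, n_subjects=30, beta_x=0.5, sigma=0.3)
        df = pd.concat(
            [df[df["timepoint"] != "A"], df[df["timepoint"] == "A"].head(5)]
        ).reset_index(drop=True)
        results, skipped = per_timepoint_models(["built"], df)
        assert "A" in skipped and "5 observations" in skipped["A"]
        assert "A" not in results

    def test_winter_only_effect_found_in_winter(self):
        found_w, found_s = 0, 0
        reps = 10
        for r in range(reps):
            rng = np.random.default_rng(600 + r)
            # effect only at W (interaction equal and opposite to main at S/A)
            df = make_glmm_data(
                rng, n_subjects=40, beta_x=0.0, sigma=0.3, interaction=(0.0, 1.2)
            )
            results, _ = per_timepoint_models(["built"], df)
            if "W" in results and results["W"][1].selected == ["built"]:
                found_w += 1
            if "S" in results and results["S"][1].selected == ["built"]:
                found_s += 1
        assert found_w >= reps * 0.7
        assert found_s <= reps * 0.4


class TestResidualDiagnostics:
    def test_nsim_precondition(self, glmm_data):
        fit = fit_glmm(ModelSpec(("built",), (), True), glmm_data)
        with pytest.raises(ValueError, match="n_sim"):
            simulate_residuals(fit, n_sim=99)

    def test_self_consistency(self):
        rng = np.random.default_rng(61)
        df = make_glmm_data(rng, n_subjects=40, beta_x=0.5, sigma=0.4)
        fit = fit_glmm(ModelSpec(("built",), (), True), df)
        diag = simulate_residuals(fit, n_sim=200, seed=1)
        assert np.all((diag.scaled_residuals >= 0) & (diag.scaled_residuals <= 1))
        assert diag.ks_p > 0.01
        assert 0.6 < diag.dispersion_ratio < 1.6

    def test_overdispersion_detected(self):
        hits = 0
        reps = 8
        for r in range(reps):
            rng = np.random.default_rng(700 + r)
            df = make_glmm_data(rng, n_subjects=40, beta_x=0.0, sigma=0.2)
            # beta-binomial contamination: huge extra variance
            p_mix = rng.beta(2, 2 * (1 / expit(-1.5) - 1), size=len(df))
            df["k"] = rng.binomial(df["n"], p_mix)
            fit = fit_glmm(ModelSpec((), (), True), df)
            diag = simulate_residuals(fit, n_sim=150, seed=r)
            hits += diag.dispersion_p < 0.05
        assert hits >= reps * 0.7


class TestLikelihoodRatioTest:
    def test_nested_fits(self, glmm_data):
        full = fit_glmm(ModelSpec(("built",), (), True), glmm_data)
        reduced = fit_glmm(ModelSpec((), (), True), glmm_data)
        lr, df, p = likelihood_ratio_test(full, reduced)
        assert lr > 0 and df == 1 and p < 0.05

    def test_requires_same_rows(self, glmm_data):
        full = fit_glmm(ModelSpec(("built",), (), True), glmm_data)
        reduced = fit_glmm(ModelSpec((), (), True), glmm_data.head(60))
        with pytest.raises(ValueError):
            likelihood_ratio_test(full, reduced)


class TestAssembleModelData:
    def test_antibiotics_excluded_by_default(self, small_study):
        from dispersalshare import run_filter_pipeline, shared_table

        covs = small_study.covariates
        covs[0].antibiotics_last_6mo["S"] = True
        rarefied, _, recs, _ = run_filter_pipeline(
            small_study.table, small_study.taxonomy, small_study.records, seed=1
        )
        srecs = shared_table(rarefied, recs)
        with_ab = assemble_model_data(srecs, covs, "saliva", exclude_antibiotics=False)
        without = assemble_model_data(srecs, covs, "saliva", exclude_antibiotics=True)
        assert len(without) == len(with_ab) - 1

    def test_missing_covariates_are_nan(self, small_study):
        from dispersalshare import run_filter_pipeline, shared_table

        covs = small_study.covariates
        covs[1].built = None
        rarefied, _, recs, _ = run_filter_pipeline(
            small_study.table, small_study.taxonomy, small_study.records, seed=1
        )
        srecs = shared_table(rarefied, recs)
        data = assemble_model_data(srecs, covs, "skin")
        assert data.loc[data["subject"] == covs[1].subject_id, "built"].isna().all()
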