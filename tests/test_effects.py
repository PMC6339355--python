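"""Effect fitting, LogWorth arithmetic, and optimum prediction."""

import numpy as np
import pandas as pd
import pytest

from operon_doe import errors
from operon_doe.design import enumerate_configurations
from operon_doe.doe import ModelSpec, design_table, encode_model_matrix
from operon_doe.effects import (
    LOGWORTH_CAP,
    effect_summary,
    fit_effects,
    logworth,
    predict_optimum,
)
from operon_doe.simulate import GroundTruth, simulate_titres


def _noise_free_table(space, design88, coef_overrides):
    """Deterministic titres from a chosen truth over the 88-run design."""
    truth = GroundTruth(sigma=0.0, alpha1=0.0, alpha0=-30.0, lod=0.0,
                        **coef_overrides)
    return truth, simulate_titres(space, design88, truth, replicates=1, seed=0)


class TestLogworth:
    def test_threshold_value_exact(self):
        assert logworth(0.01) == 2.0

    def test_p_one_is_zero(self):
        assert logworth(1.0) == 0.0

    def test_strictly_decreasing_in_p(self):
        ps = np.logspace(-8, 0, 30)
        values = [logworth(p) for p in ps]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_cap_guards_underflow(self):
        assert logworth(0.0) == LOGWORTH_CAP
        assert logworth(1e-400) == LOGWORTH_CAP


class TestFitEffects:
    def test_noiseless_promoter_coefficient_recovered(self, space, design88,
                                                      main_effects_model):
        truth, table = _noise_free_table(
            space, design88,
            dict(beta0=2.0, beta_prom=-0.5, beta_rbs=(0, 0, 0),
                 gamma_order=(0,) * 6))
        fit = fit_effects(table, space, main_effects_model)
        prom_col = fit.columns.index("promoter")
        assert fit.coefficients[prom_col] == pytest.approx(-0.5, abs=1e-10)
        assert fit.coefficients[0] == pytest.approx(2.0, abs=1e-10)

    def test_residual_df_arithmetic(self, space, design88, main_effects_model,
                                    truth88):
        # a realistic screen: failures excluded, ~41 producers, p = 10
        sim = simulate_titres(space, design88, truth88, 3, seed=99)
        fit = fit_effects(sim, space, main_effects_model)
        producers = sim.groupby("stitch_id")["detected"].any().sum()
        assert fit.n_obs == producers
        assert fit.residual_df == fit.n_obs - 10
        if fit.n_obs == 41:  # the canonical screen size
            assert fit.residual_df == 31

    def test_df_arithmetic_41_producers(self, space, design88,
                                        main_effects_model, truth88):
        # force exactly 41 producers by trimming a simulated screen
        sim = simulate_titres(space, design88, truth88, 3, seed=5)
        produced = sim.groupby("stitch_id")["detected"].any()
        keep = produced[produced].index[:41]
        table = sim[sim["stitch_id"].isin(keep) | ~sim["detected"]]
        fit = fit_effects(table, space, main_effects_model)
        assert fit.n_obs == 41 and fit.residual_df == 31

    def test_single_promoter_level_aliases(self, space, design88,
                                           main_effects_model, truth88):
        sim = simulate_titres(space, design88, truth88, 3, seed=99)
        sub = sim[sim["promoter"] == 1]
        with pytest.raises(errors.AliasingError, match="promoter"):
            fit_effects(sub, space, main_effects_model)

    def test_too_few_observations(self, space, design88, main_effects_model,
                                  truth88):
        sim = simulate_titres(space, design88, truth88, 3, seed=99)
        producers = sim[sim["detected"]]["stitch_id"].unique()[:5]
        sub = sim[sim["stitch_id"].isin(producers)]
        with pytest.raises(errors.InfeasibleFitError):
            fit_effects(sub, space, main_effects_model)

    def test_refit_on_own_predictions_is_idempotent(self, space, design88,
                                                    main_effects_model, truth88):
        sim = simulate_titres(space, design88, truth88, 3, seed=3)
        fit = fit_effects(sim, space, main_effects_model)
        # regenerate titres exactly from the fitted coefficients (sigma = 0)
        obs = sim[sim["detected"]].copy()
        configs = enumerate_configurations(space)
        sub = [configs[i] for i in sorted(obs["config_index"].unique())]
        mm = encode_model_matrix(space, sub, main_effects_model)
        pred = mm.matrix @ fit.coefficients
        lookup = dict(zip([c.config_index for c in sub], pred))
        obs["titre"] = obs["config_index"].map(lookup)
        refit = fit_effects(obs, space, main_effects_model)
        np.testing.assert_allclose(refit.coefficients, fit.coefficients,
                                   atol=1e-10)


class TestEffectSummary:
    def test_statsmodels_partial_f_agrees(self, space, design88,
                                          main_effects_model, truth88):
        """Independent cross-check of the partial F tests against statsmodels."""
        import statsmodels.api as sm

        sim = simulate_titres(space, design88, truth88, 3, seed=11)
        fit = fit_effects(sim, space, main_effects_model)
        summary = effect_summary(fit, space)
        res = sm.OLS(fit.y, fit.X).fit()
        for factor in ("promoter", "rbs_pos1", "gene_order"):
            cols = [i for i, c in enumerate(fit.columns)
                    if c == factor or c.startswith(f"{factor}[")]
            R = np.zeros((len(cols), len(fit.columns)))
            for r, c in enumerate(cols):
                R[r, c] = 1.0
            ftest = res.f_test(R)
            row = summary[factor]
            assert row["F"] == pytest.approx(float(ftest.fvalue), rel=1e-8)
            assert row["p_value"] == pytest.approx(float(ftest.pvalue), rel=1e-6)

    def test_rows_sorted_by_logworth(self, space, design88, main_effects_model,
                                     truth88):
        sim = simulate_titres(space, design88, truth88, 3, seed=11)
        fit = fit_effects(sim, space, main_effects_model)
        lw = effect_summary(fit, space).table["log_worth"].to_numpy()
        assert np.all(np.diff(lw) <= 0)

    def test_significance_flag_matches_threshold(self, space, design88,
                                                 main_effects_model, truth88):
        sim = simulate_titres(space, design88, truth88, 3, seed=11)
        fit = fit_effects(sim, space, main_effects_model)
        table = effect_summary(fit, space).table
        for _, row in table.iterrows():
            assert row["significant"] == (row["log_worth"] > 2.0)

    def test_zero_residual_variance_reports_cap(self, space, design88,
                                                main_effects_model):
        _, table = _noise_free_table(
            space, design88,
            dict(beta0=2.0, beta_prom=-0.5, beta_rbs=(0, 0, 0),
                 gamma_order=(0,) * 6))
        fit = fit_effects(table, space, main_effects_model)
        with pytest.warns(UserWarning):
            summary = effect_summary(fit, space)
        assert summary["promoter"]["log_worth"] == LOGWORTH_CAP


class TestPredictOptimum:
    def test_agrees_with_brute_force(self, space, design88, main_effects_model,
                                     truth88):
        sim = simulate_titres(space, design88, truth88, 3, seed=21)
        fit = fit_effects(sim, space, main_effects_model)
        preds = predict_optimum(fit, space, top_k=3)
        # oracle: evaluate the linear predictor over all 810 by hand
        configs = enumerate_configurations(space)
        mm = encode_model_matrix(space, configs, main_effects_model)
        all_preds = mm.matrix @ fit.coefficients
        best = np.max(all_preds)
        assert preds[0].predicted_titre == pytest.approx(best)
        assert preds[0].rank == 1

    def test_negative_effects_favor_weakest_parts(self, space, design88,
                                                  main_effects_model):
        truth, table = _noise_free_table(
            space, design88,
            dict(beta0=2.0, beta_prom=-0.6, beta_rbs=(0, 0, -0.3),
                 gamma_order=(0,) * 6))
        fit = fit_effects(table, space, main_effects_model)
        top = predict_optimum(fit, space, top_k=1)
        for p in top:
            assignment = p.configuration.assignment
            assert space.factor("promoter").value_of(assignment["promoter"]) == 1
            assert space.factor("rbs_pos3").value_of(assignment["rbs_pos3"]) == 1

    def test_order_symmetric_truth_ties(self, space, design88,
                                        main_effects_model):
        # two gene orders share the true maximum -> they tie at rank 1
        truth, table = _noise_free_table(
            space, design88,
            dict(beta0=2.0, beta_prom=-0.6, beta_rbs=(0, 0, -0.3),
                 gamma_order=(-0.5, 1.0, -0.5, 1.0, -0.5, -0.5)))
        fit = fit_effects(table, space, main_effects_model)
        top = predict_optimum(fit, space, top_k=1)
        rank1_orders = {p.configuration.assignment["gene_order"]
                        for p in top if p.rank == 1}
        assert rank1_orders == {"B-I-E", "E-I-B"}

    def test_intercept_only_model_all_tie(self, space, design88, truth88):
        model = ModelSpec(terms=(("intercept",),))
        sim = simulate_titres(space, design88, truth88, 3, seed=2)
        fit = fit_effects(sim, space, model)
        preds = predict_optimum(fit, space, top_k=1)
        assert len(preds) == 810
        assert {p.rank for p in preds} == {1}
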