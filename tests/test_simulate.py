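import numpy as np
import pytest
from scipy.special import ndtr

from zoibmed import datasets
from zoibmed.design import CoefficientSet, linear_predictors
from zoibmed.effects import EFFECT_NAMES
from zoibmed.simulate import (ScenarioSpec, generate_censored_dataset,
                              generate_zoib_dataset, lsem_effects,
                              run_simulation_study, scenario_coefficients,
                              summarize_replicates, true_effects_mc)

from conftest import intercept_only_pair
import oracles


class TestScenarios:
    @pytest.mark.parametrize("sid,mult", [(1, (1, 0)), (2, (0, 1)), (3, (10, 0)),
                                          (4, (0, 10)), (5, (1, 1))])
    def test_treatment_coefficient_overrides(self, synth_trial, sid, mult):
        coef_m, coef_y, _, _ = synth_trial
        cm, cy = scenario_coefficients(coef_m, coef_y, sid)
        my, mm = mult
        np.testing.assert_allclose(cm.treat, mm * coef_m.treat)
        np.testing.assert_allclose(cy.treat, my * coef_y.treat)
        np.testing.assert_allclose(cm.beta, coef_m.beta)  # slopes untouched

    def test_invalid_id(self, synth_trial):
        coef_m, coef_y, _, _ = synth_trial
        with pytest.raises(ValueError):
            scenario_coefficients(coef_m, coef_y, 6)


class TestZoibGenerator:
    def test_randomized_treatment_fraction(self, synth_trial):
        coef_m, coef_y, pool, scale = synth_trial
        data = generate_zoib_dataset(coef_m, coef_y, pool, 10_000, 31, scale)
        se = 0.5 / np.sqrt(10_000)
        assert abs(data.A.mean() - 0.5) < 3 * se

    def test_zero_fraction_matches_model_alpha(self, synth_trial):
        coef_m, coef_y, pool, scale = synth_trial
        data = generate_zoib_dataset(coef_m, coef_y, pool, 10_000, 32, scale)
        alpha = linear_predictors(coef_m, data.X, data.A).alpha
        p = alpha.mean()
        se = np.sqrt(p * (1 - p) / len(alpha))
        assert abs((data.M == 0).mean() - p) < 3 * se

    def test_degenerate_zero_atom(self, synth_trial):
        coef_m, coef_y, pool, scale = synth_trial
        beta = coef_m.beta.copy()
        beta[0, 0] = 30.0  # alpha intercept -> atom probability ~1
        cm = CoefficientSet("mediator", beta, np.zeros(4))
        data = generate_zoib_dataset(cm, coef_y, pool, 500, 33, scale)
        assert np.all(data.M == 0.0)


class TestCensoredGenerator:
    def test_tight_interior_latent_has_no_boundary(self, synth_trial):
        _, _, pool, scale = synth_trial
        med = np.array([0.5, 0, 0, 0, 0.0])
        out = np.array([0.5, 0, 0, 0, 0.0, 0.0])
        data = generate_censored_dataset(med, out, 1e-4, 1e-4, pool, 500, 41, scale)
        assert np.all((data.M > 0) & (data.M < 1))

    def test_far_negative_latent_all_zero(self, synth_trial):
        _, _, pool, scale = synth_trial
        med = np.array([-5.0, 0, 0, 0, 0.0])
        out = np.array([0.5, 0, 0, 0, 0.0, 0.0])
        data = generate_censored_dataset(med, out, 1.0, 0.1, pool, 2000, 42, scale)
        assert (data.M == 0).mean() > 0.99

    def test_boundary_mass_matches_normal_cdf(self, synth_trial):
        _, _, pool, scale = synth_trial
        med_lin, out_lin, med_sd, out_sd = datasets.censored_linear_coefficients()
        data = generate_censored_dataset(med_lin, out_lin, med_sd, out_sd,
                                         pool, 10_000, 43, scale)
        Zm = np.column_stack([data.X, data.A.astype(float)])
        p = ndtr((0.0 - Zm @ med_lin) / med_sd).mean()
        se = np.sqrt(p * (1 - p) / 10_000)
        assert abs((data.M == 0).mean() - p) < 3 * se + 0.005

    def test_invalid_sd(self, synth_trial):
        _, _, pool, scale = synth_trial
        with pytest.raises(ValueError):
            generate_censored_dataset(np.zeros(5), np.zeros(6), 0.0, 1.0,
                                      pool, 10, 0, scale)


class TestGroundTruth:
    def test_no_mediation_scenario_has_zero_nie(self, synth_trial):
        coef_m, coef_y, pool, scale = synth_trial
        cm, cy = scenario_coefficients(coef_m, coef_y, 1)
        truth = true_effects_mc(cm, cy, pool, 20_000, seed=1, scale=scale)
        assert truth["delta0"] == 0.0 and truth["delta1"] == 0.0

    def test_decomposition(self, synth_trial):
        coef_m, coef_y, pool, scale = synth_trial
        t = true_effects_mc(coef_m, coef_y, pool, 20_000, seed=2, scale=scale)
        assert t["tau"] == pytest.approx(t["delta0"] + t["zeta1"], abs=1e-12)

    def test_matches_quadrature_oracle_intercept_only(self):
        cm, cy = intercept_only_pair()
        pool = np.ones((10, 1))
        t = true_effects_mc(cm, cy, pool, 1_000_000, seed=3, scale=(0, 1))
        truth = oracles.mean_effects(cm, cy, np.ones((1, 1)))
        np.testing.assert_allclose(t.to_numpy(), truth, atol=1e-3)


class TestLSEM:
    @staticmethod
    def _linear_data(n, bA, cM, cA, seed):
        """Censored-normal data with negligible censoring: LSEM is correct."""
        pool = datasets.synthetic_covariate_pool(2000, seed)
        med = np.array([0.5, 0.01, 0.0, 0.0, bA])
        out = np.array([0.5, 0.01, 0.0, 0.0, cA, cM])
        return generate_censored_dataset(med, out, 0.03, 0.03, pool, n, seed,
                                         scale=(0.0, 1.0))

    def test_recovers_product_of_coefficients(self):
        bA, cM, cA = 0.08, 0.5, -0.06
        data = self._linear_data(10_000, bA, cM, cA, 51)
        eff = lsem_effects(data, seed=52)
        s = eff.draws
        assert s["delta0"].mean() == pytest.approx(bA * cM, abs=3 * s["delta0"].std())
        assert s["zeta0"].mean() == pytest.approx(cA, abs=3 * s["zeta0"].std())

    def test_null_mediator_effect_centered_at_zero(self):
        data = self._linear_data(5000, 0.08, 0.0, -0.06, 53)
        s = lsem_effects(data, seed=54).draws
        assert abs(s["delta0"].mean()) < 3 * s["delta0"].std()

    def test_effect_decomposition_exact_per_draw(self):
        data = self._linear_data(500, 0.05, 0.3, 0.0, 55)
        s = lsem_effects(data, n_draws=200, seed=56).draws
        np.testing.assert_allclose(s["delta0"] + s["zeta0"], s["tau"], atol=1e-12)
        np.testing.assert_allclose(s["delta0"], s["delta1"])


class TestMetrics:
    def test_degenerate_truth_teller_with_zero_width_intervals(self):
        truth = np.array([0.1, 0.2, -0.3, 0.0, 0.4])
        est = np.tile(truth, (3, 1))
        tab = summarize_replicates(est, est + 1e-6, est + 2e-6, truth)
        np.testing.assert_allclose(tab["bias"], 0.0, atol=1e-9)
        np.testing.assert_allclose(tab["rmse"], 0.0, atol=1e-9)
        np.testing.assert_allclose(tab["coverage"], 0.0)

    def test_constant_offset_estimator(self):
        truth = np.zeros(5)
        d = 0.02
        est = np.full((4, 5), d)
        tab = summarize_replicates(est, est - 0.001, est + 0.001, truth)
        np.testing.assert_allclose(tab["bias"], 100 * d)
        np.testing.assert_allclose(tab["rmse"], 100 * d)

    def test_hand_built_three_replicates(self):
        truth = np.array([0.0, 0.0, 0.0, 0.0, 0.0])
        est = np.array([[0.01], [0.03], [-0.01]]) * np.ones((1, 5))
        lower = est - 0.02
        upper = est + 0.02
        tab = summarize_replicates(est, lower, upper, truth)
        assert tab["bias"].iloc[0] == pytest.approx(100 * 0.01)
        assert tab["rmse"].iloc[0] == pytest.approx(100 * np.sqrt((0.0001 + 0.0009 + 0.0001) / 3))
        assert tab["coverage"].iloc[0] == pytest.approx(100 * 2 / 3)
        assert tab["length"].iloc[0] == pytest.approx(100 * 0.04)

    def test_rmse_decomposes_into_bias_and_variance(self, synth_trial):
        coef_m, coef_y, pool, scale = synth_trial
        spec = ScenarioSpec(coef_m, coef_y, pool, scenario_id=5, n=400, scale=scale)
        rep = run_simulation_study(spec, n_reps=6, estimator="lsem", seed=61)
        est = rep.estimates.to_numpy()
        truth = rep.table["truth"].to_numpy() / 100
        bias = rep.table["bias"].to_numpy() / 100
        rmse = rep.table["rmse"].to_numpy() / 100
        var = est.var(axis=0)
        np.testing.assert_allclose(rmse**2, bias**2 + var, rtol=1e-8)
        assert np.all(rmse >= np.abs(bias) - 1e-12)


class TestStudyHarness:
    def test_lsem_study_runs_and_reports(self, synth_trial):
        coef_m, coef_y, pool, scale = synth_trial
        spec = ScenarioSpec(coef_m, coef_y, pool, scenario_id=1, n=300, scale=scale)
        rep = run_simulation_study(spec, n_reps=3, estimator="lsem", seed=62)
        assert rep.n_reps == 3 and rep.n_failed == 0
        assert list(rep.table.index) == list(EFFECT_NAMES)
        assert set(rep.table.columns) == {"truth", "bias", "rmse", "coverage", "length"}
        assert np.isfinite(rep.table.to_numpy()).all()

    def test_bad_estimator_rejected(self, synth_trial):
        coef_m, coef_y, pool, scale = synth_trial
        spec = ScenarioSpec(coef_m, coef_y, pool, scenario_id=1, n=100, scale=scale)
        with pytest.raises(ValueError):
            run_simulation_study(spec, n_reps=1, estimator="sem", seed=0)
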