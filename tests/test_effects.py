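import numpy as np
import pytest
from scipy import stats

from zoibmed.design import CoefficientSet
from zoibmed.effects import (EFFECT_NAMES, average_effects, mc_error_estimate,
                             quantile_effects, simulate_potential_mediators,
                             weighted_quantile)
from zoibmed.zoib import ZoibParams, zoib_rng

from conftest import draws_from_coeffs, intercept_only_pair
import oracles


class TestPotentialMediators:
    def test_zero_treatment_effect_gives_identical_arms(self):
        cm = CoefficientSet("mediator", np.array([[-2.0], [-1.0], [0.4], [1.5]]),
                            np.zeros(4))
        m0, m1 = simulate_potential_mediators(cm, np.ones((20, 1)), K=4, seed=0)
        assert np.array_equal(m0, m1)

    def test_large_zero_atom_forces_zero_draws(self):
        cm = CoefficientSet("mediator", np.array([[30.0], [0.0], [0.0], [1.0]]),
                            np.zeros(4))
        m0, m1 = simulate_potential_mediators(cm, np.ones((50, 1)), K=2, seed=1)
        assert np.all(m0 == 0.0) and np.all(m1 == 0.0)

    def test_marginal_matches_direct_sampling(self):
        cm, _ = intercept_only_pair()
        m0, _ = simulate_potential_mediators(cm, np.ones((20_000, 1)), K=1, seed=2)
        from zoibmed.design import linear_predictors
        p = linear_predictors(cm, np.ones((1, 1)), 0)
        ref = zoib_rng(ZoibParams(p.alpha[0], p.gamma[0], p.mu[0], p.phi[0]),
                       20_000, seed=3)
        x, y = m0.ravel(), ref
        ks = stats.ks_2samp(x[(x > 0) & (x < 1)], y[(y > 0) & (y < 1)])
        assert ks.pvalue > 1e-3
        assert abs((x == 0).mean() - (y == 0).mean()) < 0.02


class TestAverageEffects:
    def test_no_mediator_pathway_gives_exact_zero_nie(self, toy_data):
        cm, cy = intercept_only_pair(out_med=(0.0, 0.0, 0.0, 0.0))
        draws = draws_from_coeffs([(cm, cy)] * 3)
        eff = average_effects(draws, toy_data, K=2, seed=0)
        assert np.all(eff.draws["delta0"] == 0.0)
        assert np.all(eff.draws["delta1"] == 0.0)

    def test_decomposition_identity_per_draw(self, fitted_draws, synth_data):
        eff = average_effects(fitted_draws.thin(50), synth_data, K=2, seed=1)
        d = eff.draws
        np.testing.assert_allclose(d["delta1"] + d["zeta0"], d["tau"], atol=1e-12)
        np.testing.assert_allclose(d["delta0"] + d["zeta1"], d["tau"], atol=1e-12)

    def test_matches_quadrature_oracle_intercept_only(self, toy_data):
        cm, cy = intercept_only_pair()
        draws = draws_from_coeffs([(cm, cy)])
        eff = average_effects(draws, toy_data, K=64, seed=2)
        truth = oracles.mean_effects(cm, cy, np.ones((1, 1)))
        est = eff.draws.iloc[0].to_numpy()
        # Monte-Carlo error: replicate noise + bootstrap-weight noise
        mc = eff.mc_se.iloc[0].to_numpy()
        assert np.all(np.abs(est - truth) < 3 * np.maximum(mc, 0.004))

    def test_rao_blackwell_reduces_variance(self, toy_data):
        cm, cy = intercept_only_pair()
        draws = draws_from_coeffs([(cm, cy)])
        rb, raw = [], []
        for s in range(40):
            rb.append(average_effects(draws, toy_data, K=2, seed=s).draws.iloc[0])
            raw.append(average_effects(draws, toy_data, K=2, seed=s,
                                       rao_blackwell=False).draws.iloc[0])
        v_rb = np.array(rb).var(axis=0)
        v_raw = np.array(raw).var(axis=0)
        assert np.all(v_rb < v_raw)

    def test_null_model_centers_at_zero(self, synth_trial):
        from zoibmed import MCMCConfig, fit_posterior
        from zoibmed.simulate import generate_zoib_dataset

        coef_m, coef_y, pool, scale = synth_trial
        cm = CoefficientSet("mediator", coef_m.beta.copy(), np.zeros(4))
        cy = CoefficientSet("outcome", coef_y.beta.copy(), np.zeros(4),
                            coef_y.med.copy())
        data = generate_zoib_dataset(cm, cy, pool, 1500, 17, scale)
        draws = fit_posterior(data, mcmc=MCMCConfig(seed=18, chains=4,
                                                    iterations=250, warmup=125))
        eff = average_effects(draws, data, K=2, seed=19)
        for name in EFFECT_NAMES:
            x = eff.draws[name]
            assert abs(x.mean()) < 3 * x.std()

    def test_invalid_k(self, fitted_draws, synth_data):
        with pytest.raises(ValueError):
            average_effects(fitted_draws, synth_data, K=0)


class TestMonteCarloError:
    def test_degenerate_mediator_gives_zero_error(self, toy_data):
        cm = CoefficientSet("mediator", np.array([[30.0], [0.0], [0.0], [1.0]]),
                            np.zeros(4))
        _, cy = intercept_only_pair()
        draws = draws_from_coeffs([(cm, cy)])
        eff = average_effects(draws, toy_data, K=4, seed=0)
        assert np.all(eff.mc_se.to_numpy() == 0.0)

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError, match="K >= 2"):
            mc_error_estimate(np.zeros((1, 1, 5)), K=1)

    def test_error_shrinks_with_replicates(self, toy_data):
        cm, cy = intercept_only_pair()
        draws = draws_from_coeffs([(cm, cy)] * 20)
        e1 = average_effects(draws, toy_data, K=8, seed=3).mc_se.median()
        e2 = average_effects(draws, toy_data, K=16, seed=3).mc_se.median()
        ratio = (e2 / e1).median()
        assert 0.5 < ratio < 0.95  # about 1/sqrt(2), generous band

    def test_error_consistent_with_rerun_scatter(self, toy_data):
        cm, cy = intercept_only_pair()
        draws = draws_from_coeffs([(cm, cy)])
        ests, errs = [], []
        for s in range(20):
            eff = average_effects(draws, toy_data, K=4, seed=s)
            ests.append(eff.draws.iloc[0]["delta0"])
            errs.append(eff.mc_se.iloc[0]["delta0"])
        # reruns also redraw bootstrap weights, so the replicate-based error
        # can only account for part of the scatter but must be the right order
        emp = np.std(ests)
        assert np.median(errs) < 3 * emp


class TestQuantileEffects:
    def test_no_mediator_pathway_gives_exact_zero(self, toy_data):
        cm, cy = intercept_only_pair(out_med=(0.0, 0.0, 0.0, 0.0))
        draws = draws_from_coeffs([(cm, cy)] * 2)
        eff = quantile_effects(draws, toy_data, K=5, q=0.5, seed=0)
        assert np.all(eff.draws["delta0"] == 0.0)
        assert np.all(eff.draws["delta1"] == 0.0)

    def test_quantile_decomposition_identity(self, fitted_draws, synth_data):
        eff = quantile_effects(fitted_draws.thin(20), synth_data, K=5, q=0.5, seed=1)
        d = eff.draws
        np.testing.assert_allclose(d["delta1"] + d["zeta0"], d["tau"], atol=1e-12)
        np.testing.assert_allclose(d["delta0"] + d["zeta1"], d["tau"], atol=1e-12)

    def test_matches_brute_force_oracle(self, toy_data):
        cm, cy = intercept_only_pair()
        draws = draws_from_coeffs([(cm, cy)])
        ests = np.stack([
            quantile_effects(draws, toy_data, K=10, q=0.5, seed=s).draws.iloc[0]
            for s in range(12)])
        truth = oracles.brute_force_quantile_effects(
            cm, cy, np.ones((1, 1)), q=0.5, n_sim=200_000, seed=99)
        err = np.abs(ests.mean(axis=0) - truth)
        tol = 3 * ests.std(axis=0) / np.sqrt(12) + 0.01
        assert np.all(err < tol)

    def test_resampling_mode_agrees_in_expectation(self, toy_data):
        cm, cy = intercept_only_pair()
        draws = draws_from_coeffs([(cm, cy)] * 10)
        a = quantile_effects(draws, toy_data, K=10, q=0.5, seed=2)
        b = quantile_effects(draws, toy_data, K=10, q=0.5, seed=2,
                             resample_covariates=True)
        assert abs(a.draws["tau"].mean() - b.draws["tau"].mean()) < 0.05

    def test_boundary_quantile_rejected(self, fitted_draws, synth_data):
        with pytest.raises(ValueError):
            quantile_effects(fitted_draws, synth_data, q=0.0)

    def test_quantile_effects_integrate_to_mean_total_effect(self, toy_data):
        """Integrating Qq(F11) - Qq(F00) over q recovers the mean tau."""
        cm, cy = intercept_only_pair()
        draws = draws_from_coeffs([(cm, cy)])
        qs = np.linspace(0.005, 0.995, 199)
        taus = [quantile_effects(draws, toy_data, K=40, q=float(q), seed=7)
                .draws.iloc[0]["tau"] for q in qs]
        integral = np.trapezoid(taus, qs)
        mean_tau = average_effects(draws, toy_data, K=40, seed=7).draws.iloc[0]["tau"]
        assert integral == pytest.approx(mean_tau, abs=0.02)


class TestWeightedQuantile:
    def test_left_continuous_inverse(self):
        v = np.array([1.0, 2.0, 3.0])
        w = np.array([0.25, 0.5, 0.25])
        assert weighted_quantile(v, w, 0.25) == 1.0
        assert weighted_quantile(v, w, 0.2500001) == 2.0
        assert weighted_quantile(v, w, 0.75) == 2.0
        assert weighted_quantile(v, w, 0.9) == 3.0

    def test_matches_numpy_on_uniform_weights(self):
        rng = np.random.default_rng(0)
        v = rng.normal(size=501)
        w = np.full(501, 1 / 501)
        for q in (0.1, 0.5, 0.9):
            assert abs(weighted_quantile(v, w, q) - np.quantile(v, q)) < 0.02
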