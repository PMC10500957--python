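"""Synthetic-data generators and the simulation-study harness.

Five scenarios modify the treatment coefficients (xi_Y, xi_M) of a base
coefficient set:

    1  no mediation            (xi_Y,      0)
    2  complete mediation      (0,         xi_M)
    3  strong no mediation     (10 xi_Y,   0)
    4  strong complete med.    (0,         10 xi_M)
    5  no modifications        (xi_Y,      xi_M)

Datasets are generated by resampling covariate rows from a pool, randomizing
treatment with probability 1/2, and drawing the mediator and outcome from the
ZOIB GLMs (or from a censored-normal mechanism for misspecification studies).
Ground-truth effects come from a large Rao-Blackwellized Monte-Carlo pass with
uniform covariate weights.  Operating characteristics (bias, RMSE, coverage and
length of nominal 95% intervals, all x100) are aggregated over replicates, with
a linear structural equation model (LSEM, product-of-coefficients) comparator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .design import CoefficientSet, MediationDataset, linear_predictors
from .effects import (EFFECT_NAMES, MediationEffects, _ebar_rb,
                      _effects_from_ebar, _mediator_pairs, average_effects)
from .inference import MCMCConfig, fit_posterior
from .zoib import ZoibParams

__all__ = [
    "ScenarioSpec",
    "SimulationReport",
    "scenario_coefficients",
    "generate_zoib_dataset",
    "generate_censored_dataset",
    "true_effects_mc",
    "lsem_effects",
    "run_simulation_study",
]

_SCENARIO_MULT = {1: (1.0, 0.0), 2: (0.0, 1.0), 3: (10.0, 0.0), 4: (0.0, 10.0), 5: (1.0, 1.0)}


@dataclass
class ScenarioSpec:
    """One simulation scenario: base coefficients + id + sample size."""

    coef_m: CoefficientSet
    coef_y: CoefficientSet
    pool: np.ndarray
    scenario_id: int = 5
    n: int = 899
    scale: tuple = (1.0, 5.0)

    def coefficients(self):
        return scenario_coefficients(self.coef_m, self.coef_y, self.scenario_id)


def scenario_coefficients(coef_m: CoefficientSet, coef_y: CoefficientSet,
                          scenario_id: int):
    """Apply the scenario's (xi_Y, xi_M) multipliers to the treatment coefficients."""
    if scenario_id not in _SCENARIO_MULT:
        raise ValueError("scenario id must be in 1..5")
    my, mm = _SCENARIO_MULT[scenario_id]
    return coef_m.replace_treat(mm * coef_m.treat), coef_y.replace_treat(my * coef_y.treat)


def _draw_zoib_rows(params: ZoibParams, rng) -> np.ndarray:
    n = params.alpha.shape[0]
    u0, u1 = rng.uniform(size=n), rng.uniform(size=n)
    body = rng.beta(params.shape_a, params.shape_b)
    return np.where(u0 < params.alpha, 0.0, np.where(u1 < params.gamma, 1.0, body))


def generate_zoib_dataset(coef_m: CoefficientSet, coef_y: CoefficientSet,
                          pool: np.ndarray, n: int, seed,
                          scale: tuple = (1.0, 5.0)) -> MediationDataset:
    """Simulate a trial: X resampled from the pool, A ~ Bernoulli(1/2),
    M ~ ZOIB(mediator GLM), Y ~ ZOIB(outcome GLM)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = pool[rng.integers(0, pool.shape[0], size=n)]
    A = (rng.uniform(size=n) < 0.5).astype(int)
    M = _draw_zoib_rows(linear_predictors(coef_m, X, A), rng)
    Y = _draw_zoib_rows(linear_predictors(coef_y, X, A, M), rng)
    return MediationDataset(X=X, A=A, M=M, Y=Y, m_scale=scale, y_scale=scale)


def generate_censored_dataset(med_lin: np.ndarray, out_lin: np.ndarray,
                              med_sd: float, out_sd: float, pool: np.ndarray,
                              n: int, seed, scale: tuple = (1.0, 5.0)) -> MediationDataset:
    """Censored-normal alternative mechanism.

    Latent M' = [X, A] @ med_lin + N(0, med_sd^2) and
    Y' = [X, A, M] @ out_lin + N(0, out_sd^2); observed values clamp latents
    below 0 to 0 and above 1 to 1.
    """
    if med_sd <= 0 or out_sd <= 0:
        raise ValueError("error standard deviations must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    X = pool[rng.integers(0, pool.shape[0], size=n)]
    A = (rng.uniform(size=n) < 0.5).astype(int)
    Zm = np.column_stack([X, A.astype(float)])
    M_lat = Zm @ med_lin + med_sd * rng.standard_normal(n)
    M = np.clip(M_lat, 0.0, 1.0)
    Zy = np.column_stack([X, A.astype(float), M])
    Y_lat = Zy @ out_lin + out_sd * rng.standard_normal(n)
    Y = np.clip(Y_lat, 0.0, 1.0)
    return MediationDataset(X=X, A=A, M=M, Y=Y, m_scale=scale, y_scale=scale)


def true_effects_mc(coef_m: CoefficientSet, coef_y: CoefficientSet,
                    pool: np.ndarray, n_mc: int, seed: int = 0,
                    scale: tuple = (1.0, 5.0)) -> pd.Series:
    """Ground-truth effects by large Rao-Blackwellized Monte Carlo.

    Uniform weights over ``n_mc`` covariate draws, comonotone mediator
    coupling, no posterior uncertainty.  Returns the five effects on the
    original scale.
    """
    if n_mc < 1:
        raise ValueError("n_mc must be >= 1")
    rng = np.random.default_rng(seed)
    X = pool[rng.integers(0, pool.shape[0], size=n_mc)]
    m0, m1 = _mediator_pairs(rng, coef_m, X, 1)
    eb = {k: float(v.mean()) for k, v in _ebar_rb(coef_y, X, m0, m1).items()}
    lo, hi = scale
    vals = _effects_from_ebar(eb) * (hi - lo)
    return pd.Series(vals, index=list(EFFECT_NAMES))


def lsem_effects(data: MediationDataset, n_draws: int = 2000, seed: int = 0) -> MediationEffects:
    """Linear structural equation model comparator (product of coefficients).

    Fits M = [X, A] b + e and Y = [X, A, M] c + e' and samples the flat-prior
    (Jeffreys) Bayesian linear regression posterior of both in closed form.
    Per draw: delta(0) = delta(1) = b_A * c_M, zeta = c_A, tau = b_A c_M + c_A,
    reported on the original outcome scale.
    """
    rng = np.random.default_rng(seed)
    lo, hi = data.y_scale

    def posterior_beta(Z, y):
        n, k = Z.shape
        ZtZ = Z.T @ Z
        try:
            ZtZ_inv = np.linalg.inv(ZtZ)
        except np.linalg.LinAlgError as e:
            raise ValueError("singular design in LSEM fit") from e
        bhat = ZtZ_inv @ Z.T @ y
        resid = y - Z @ bhat
        s2 = resid @ resid
        sigma2 = s2 / rng.chisquare(n - k, size=n_draws)
        L = np.linalg.cholesky(ZtZ_inv)
        eps = rng.standard_normal((n_draws, k))
        return bhat + np.sqrt(sigma2)[:, None] * (eps @ L.T)

    Zm = np.column_stack([data.X, data.A.astype(float)])
    Zy = np.column_stack([data.X, data.A.astype(float), data.M])
    bm = posterior_beta(Zm, data.M)
    cy = posterior_beta(Zy, data.Y)
    bA = bm[:, -1]
    cA, cM = cy[:, -2], cy[:, -1]
    delta = bA * cM * (hi - lo)
    zeta = cA * (hi - lo)
    df = pd.DataFrame({
        "delta0": delta, "delta1": delta,
        "zeta0": zeta, "zeta1": zeta,
        "tau": delta + zeta,
    })
    return MediationEffects(df, (lo, hi), meta={"estimator": "lsem"})


@dataclass
class SimulationReport:
    """Operating characteristics per effect, everything x100."""

    table: pd.DataFrame  # index: effect; columns truth, bias, rmse, coverage, length
    n_reps: int
    n_failed: int = 0
    estimates: pd.DataFrame | None = None  # per-replicate point estimates
    meta: dict = field(default_factory=dict)


def summarize_replicates(est: np.ndarray, lower: np.ndarray, upper: np.ndarray,
                         truth: np.ndarray) -> pd.DataFrame:
    """Aggregate replicate estimates/intervals into the x100 metrics table."""
    bias = (est - truth).mean(axis=0)
    rmse = np.sqrt(((est - truth) ** 2).mean(axis=0))
    coverage = ((lower <= truth) & (truth <= upper)).mean(axis=0)
    length = (upper - lower).mean(axis=0)
    return pd.DataFrame({
        "truth": truth * 100, "bias": bias * 100, "rmse": rmse * 100,
        "coverage": coverage * 100, "length": length * 100,
    }, index=list(EFFECT_NAMES))


def run_simulation_study(spec: ScenarioSpec, n_reps: int, estimator: str = "zoib",
                         mcmc: MCMCConfig | None = None, seed: int = 0,
                         K: int = 2, n_mc: int | None = None,
                         prior_sd: float = 10.0) -> SimulationReport:
    """Repeated-sampling evaluation of an estimator under one scenario.

    Per replicate: generate a dataset from the scenario coefficients, fit the
    chosen estimator ('zoib' = ZOIB posterior + g-formula, 'lsem' = linear SEM
    comparator), record the posterior mean and central 95% interval of each
    effect; aggregate bias/RMSE/coverage/mean length against the ground truth
    (computed once with ``n_mc`` Monte-Carlo samples, default 101 * n).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if estimator not in ("zoib", "lsem"):
        raise ValueError("estimator must be 'zoib' or 'lsem'")
    coef_m, coef_y = spec.coefficients()
    n_mc = n_mc or 101 * spec.n
    truth = true_effects_mc(coef_m, coef_y, spec.pool, n_mc, seed=seed + 90799,
                            scale=spec.scale).to_numpy()
    est = np.empty((n_reps, 5))
    lower = np.empty((n_reps, 5))
    upper = np.empty((n_reps, 5))
    failed = 0
    kept = 0
    for r in range(n_reps):
        rng = np.random.default_rng([seed, r])
        data = generate_zoib_dataset(coef_m, coef_y, spec.pool, spec.n, rng,
                                     scale=spec.scale)
        try:
            if estimator == "zoib":
                cfg = mcmc or MCMCConfig(chains=4, iterations=250, warmup=125,
                                         seed=int(rng.integers(2**31 - 1)))
                draws = fit_posterior(data, prior_sd=prior_sd, mcmc=cfg)
                eff = average_effects(draws, data, K=K, seed=int(rng.integers(2**31 - 1)))
            else:
                eff = lsem_effects(data, seed=int(rng.integers(2**31 - 1)))
        except Exception:
            failed += 1
            continue
        x = eff.draws.to_numpy()
        est[kept] = x.mean(axis=0)
        lower[kept] = np.quantile(x, 0.025, axis=0)
        upper[kept] = np.quantile(x, 0.975, axis=0)
        kept += 1
    if kept == 0:
        raise RuntimeError("all replicates failed")
    table = summarize_replicates(est[:kept], lower[:kept], upper[:kept], truth)
    return SimulationReport(table, n_reps=kept, n_failed=failed,
                            estimates=pd.DataFrame(est[:kept], columns=list(EFFECT_NAMES)),
                            meta={"scenario": spec.scenario_id, "estimator": estimator,
                                  "n": spec.n, "K": K})
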