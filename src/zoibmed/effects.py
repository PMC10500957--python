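"""Monte-Carlo g-formula estimation of average and quantile mediation effects.

For each posterior coefficient draw the estimators below:

1. draw Bayesian-bootstrap weights omega ~ Dirichlet(1, ..., 1) over the
   observed covariate rows (the posterior of the covariate distribution F_X);
2. draw K replicate potential mediators per subject through the probability
   integral transform, M*_ik(a) = F_M^-(U_ik | a, X_i), with a single uniform
   U_ik shared across arms (comonotone coupling) so that marginal contrasts
   carry minimal Monte-Carlo noise;
3. form the four counterfactual means E-bar(a, a') and assemble

       delta(a) = E[Y{a, M(1)}] - E[Y{a, M(0)}]   (natural indirect effect)
       zeta(a)  = E[Y{1, M(a)}] - E[Y{0, M(a)}]   (natural direct effect)
       tau      = delta(1) + zeta(0) = delta(0) + zeta(1)

The average-effect estimator is Rao-Blackwellized by default: the simulated
outcome Y*{a, M*(a')} is replaced by its conditional ZOIB mean given
(M*(a'), a, X_i), which strictly reduces Monte-Carlo variance.  Quantile
effects cannot be Rao-Blackwellized; they use comonotone outcome uniforms V
and omega-weighted empirical distributions with atoms of weight omega_i / K.

Effects are reported on the original outcome scale (multiplied by hi - lo).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .design import MediationDataset, linear_predictors
from .inference import PosteriorDraws, sample_bb_weights
from .zoib import zoib_mean, zoib_quantile

__all__ = [
    "EFFECT_NAMES",
    "MediationEffects",
    "QuantileEffects",
    "simulate_potential_mediators",
    "average_effects",
    "quantile_effects",
    "mc_error_estimate",
    "weighted_quantile",
]

EFFECT_NAMES = ("delta0", "delta1", "zeta0", "zeta1", "tau")


@dataclass
class MediationEffects:
    """Per-posterior-draw mediation effects plus Monte-Carlo error estimates.

    ``draws`` has one row per posterior draw and columns
    (delta0, delta1, zeta0, zeta1, tau) on the original outcome scale.
    """

    draws: pd.DataFrame
    scale: tuple = (0.0, 1.0)
    mc_se: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        """Posterior mean, sd, central 95% interval, Z-score, normal p-value."""
        from .report import effects_table

        return effects_table(self)


@dataclass
class QuantileEffects:
    """Per-posterior-draw quantile mediation effects at quantile q."""

    draws: pd.DataFrame
    q: float
    scale: tuple = (0.0, 1.0)
    meta: dict = field(default_factory=dict)

    def summary(self) -> pd.DataFrame:
        from .report import effects_table

        return effects_table(self)


def _mediator_pairs(rng, coef_m, X, K, rho=1.0):
    """Potential mediator replicates (M0, M1), each (N, K).

    ``rho`` is the Gaussian-copula correlation of the underlying normals;
    rho = 1 is the comonotone coupling (a single shared uniform per (i, k)).
    The per-arm marginals are invariant to rho.
    """
    n = X.shape[0]
    e0 = rng.standard_normal((n, K))
    e1 = rng.standard_normal((n, K))  # always drawn: keeps the rng stream aligned
    z0 = e0
    z1 = rho * e0 + np.sqrt(max(0.0, 1.0 - rho**2)) * e1
    u0, u1 = ndtr(z0), ndtr(z1)
    p0 = linear_predictors(coef_m, X, 0)
    p1 = linear_predictors(coef_m, X, 1)
    m0 = zoib_quantile(u0, _bcast(p0, K))
    m1 = zoib_quantile(u1, _bcast(p1, K))
    return m0, m1


def _bcast(params, K):
    from .zoib import ZoibParams

    return ZoibParams(params.alpha[:, None], params.gamma[:, None],
                      params.mu[:, None], params.phi[:, None])


def simulate_potential_mediators(coef_m, X, K: int, seed, rho: float = 1.0):
    """Draw comonotone (or rho-coupled) potential mediators for one coefficient draw."""
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _mediator_pairs(rng, coef_m, X, K, rho)


def _ebar_rb(coef_y, X, m0, m1):
    """Rao-Blackwellized conditional outcome means r_y for the 4 (a, a') combos.

    Returns dict (a, aprime) -> (N, K) array of E[Y | M* (aprime), a, X].
    """
    out = {}
    for a in (0, 1):
        for ap, m in ((0, m0), (1, m1)):
            out[(a, ap)] = zoib_mean(linear_predictors(coef_y, X, a, m))
    return out


def _effects_from_ebar(eb):
    """Assemble (delta0, delta1, zeta0, zeta1, tau) from the four E-bar values."""
    return np.array([
        eb[(0, 1)] - eb[(0, 0)],
        eb[(1, 1)] - eb[(1, 0)],
        eb[(1, 0)] - eb[(0, 0)],
        eb[(1, 1)] - eb[(0, 1)],
        eb[(1, 1)] - eb[(0, 0)],
    ])


def average_effects(draws: PosteriorDraws, data: MediationDataset, K: int = 2,
                    seed: int = 0, rao_blackwell: bool = True,
                    rho: float = 1.0) -> MediationEffects:
    """Average mediation effects per posterior draw via the Monte-Carlo g-formula.

    ``rho`` sets the coupling of the potential-mediator pair (1 = comonotone
    default; it changes only the Monte-Carlo error, not the estimand).  With
    ``rao_blackwell=False`` the raw simulated-outcome estimator is used (kept
    for variance comparisons); both share the mediator draws.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    lo, hi = data.y_scale
    rows = np.empty((draws.B, 5))
    contrib = np.empty((draws.B, K, 5))  # per-replicate effect contributions
    for b in range(draws.B):
        rng = np.random.default_rng([seed, b])
        omega = sample_bb_weights(data.n, rng).weights
        coef_m, coef_y = draws.coefficient_sets(b)
        m0, m1 = _mediator_pairs(rng, coef_m, data.X, K, rho)
        if rao_blackwell:
            vals = _ebar_rb(coef_y, data.X, m0, m1)
        else:
            v = rng.uniform(size=(data.n, K))
            vals = {}
            for a in (0, 1):
                for ap, m in ((0, m0), (1, m1)):
                    py = linear_predictors(coef_y, data.X, a, m)
                    vals[(a, ap)] = zoib_quantile(v, py)
        eb_k = {k: omega @ v for k, v in vals.items()}  # (K,) per combo
        eff_k = _effects_from_ebar(eb_k)  # (5, K)
        contrib[b] = eff_k.T * (hi - lo)
        rows[b] = eff_k.mean(axis=1) * (hi - lo)
    df = pd.DataFrame(rows, columns=list(EFFECT_NAMES))
    mc = mc_error_estimate(contrib, K) if K >= 2 else None
    return MediationEffects(df, (lo, hi), mc, meta={"K": K, "seed": seed, "rho": rho,
                                                    "rao_blackwell": rao_blackwell})


def mc_error_estimate(contrib: np.ndarray, K: int) -> pd.DataFrame:
    """Monte-Carlo standard error of each effect from per-replicate contributions.

    ``contrib`` is (B, K, 5): the effect estimate computed from each of the K
    replicates separately.  The MC error of the K-replicate average is
    sqrt(var_k / K); it should be well below the posterior sd.
    """
    if K < 2:
        raise ValueError("Monte-Carlo error assessment requires K >= 2")
    se = np.sqrt(contrib.var(axis=1, ddof=1) / K)  # (B, 5)
    return pd.DataFrame(se, columns=list(EFFECT_NAMES))


def weighted_quantile(values: np.ndarray, weights: np.ndarray, q: float) -> float:
    """Generalized inverse of the weighted ECDF: inf{y : F(y) >= q}."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    cw = np.cumsum(weights[order])
    cw /= cw[-1]
    idx = np.searchsorted(cw, q, side="left")
    return float(v[min(idx, len(v) - 1)])


def quantile_effects(draws: PosteriorDraws, data: MediationDataset, K: int = 10,
                     q: float = 0.5, seed: int = 0,
                     resample_covariates: bool = False) -> QuantileEffects:
    """Quantile mediation effects per posterior draw.

    Comonotone uniforms U (mediator) and V (outcome) are shared across the four
    (a, a') combinations; each combination's marginal distribution is the
    omega-weighted empirical distribution with atoms of weight omega_i / K.
    With ``resample_covariates=True`` covariate rows are literally resampled
    according to omega instead (higher Monte-Carlo error, same target).
    """
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie strictly inside (0, 1)")
    if K < 1:
        raise ValueError("K must be >= 1")
    lo, hi = data.y_scale
    rows = np.empty((draws.B, 5))
    for b in range(draws.B):
        rng = np.random.default_rng([seed + 1_000_003, b])
        omega = sample_bb_weights(data.n, rng).weights
        coef_m, coef_y = draws.coefficient_sets(b)
        if resample_covariates:
            idx = rng.choice(data.n, size=data.n, p=omega)
            X = data.X[idx]
            w = np.full(data.n, 1.0 / data.n)
        else:
            X = data.X
            w = omega
        m0, m1 = _mediator_pairs(rng, coef_m, X, K)
        v = ndtr(rng.standard_normal((X.shape[0], K)))
        atoms_w = np.repeat(w / K, K)
        qv = {}
        for a in (0, 1):
            for ap, m in ((0, m0), (1, m1)):
                py = linear_predictors(coef_y, X, a, m)
                y = zoib_quantile(v, py)
                qv[(a, ap)] = weighted_quantile(y.ravel(), atoms_w, q)
        rows[b] = _effects_from_ebar(qv) * (hi - lo)
    df = pd.DataFrame(rows, columns=list(EFFECT_NAMES))
    return QuantileEffects(df, q, (lo, hi),
                           meta={"K": K, "seed": seed, "resample": resample_covariates})
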