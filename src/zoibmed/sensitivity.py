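"""Sensitivity analysis for unmeasured mediator-outcome confounding.

Sequential ignorability's second condition (mediator assignment ignorable given
treatment and covariates) is replaced by two weaker, deliberately unidentified
assumptions:

* the potential mediators (M(0), M(1)) follow a Gaussian copula with
  correlation rho in [0, 1], each margin being the fitted mediator model;
* the conditional mean of Y(a, m) given the mediator pair is shifted on the
  logit scale by lambda * (M(a) - m) relative to the observed-data conditional
  mean r_y(m, a, x) = E[Y | M = m, A = a, X = x].

Both lambda and rho are *pure* sensitivity parameters: the observed-data
likelihood never sees them, lambda = 0 reproduces the sequential-ignorability
estimates exactly (under shared seeds), and every within-arm mean E-bar(a, a)
— hence the total effect tau — is invariant to (lambda, rho).

The estimator mirrors the Rao-Blackwellized g-formula average:

    E-bar(a, a') = K^-1 sum_{i,k} omega_i
                   * expit[ logit r_y(M*_ik(a'), a, X_i)
                            + lambda * (M*_ik(a) - M*_ik(a')) ]

with copula-coupled mediator pairs (comonotone coupling is *not* used when
rho < 1, because rho is part of the assumed model, not a computational device).

The plausible lambda range is calibrated from a pilot quasi-likelihood
logit-link regression of Y on (X, A, M): the default grid spans
[-2 |beta_M|, +2 |beta_M|] where beta_M is the pilot mediator slope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .design import MediationDataset
from .effects import (EFFECT_NAMES, MediationEffects, _ebar_rb,
                      _effects_from_ebar, _mediator_pairs)
from .inference import PosteriorDraws, sample_bb_weights

__all__ = [
    "SensitivityParams",
    "SensitivityCurve",
    "copula_mediator_pairs",
    "sensitivity_average_effects",
    "calibrate_lambda",
    "sensitivity_grid",
]

_EPS = 1e-12  # clamp for logit(r_y)


@dataclass(frozen=True)
class SensitivityParams:
    """(lambda, rho) sensitivity point; lam is the logit-scale shift."""

    lam: float = 0.0
    rho: float = 0.95

    def __post_init__(self):
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if not np.isfinite(self.lam):
            raise ValueError("lambda must be finite")


@dataclass
class SensitivityCurve:
    """Tidy effect summaries over a (lambda, rho) grid.

    ``table`` columns: rho, lam, effect, mean, sd, lower, upper.
    """

    table: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def plot(self, effects=("delta0", "delta1", "zeta0", "zeta1"), ax=None):
        """Line (posterior mean) + band (95% pointwise credible interval) vs lambda."""
        import matplotlib.pyplot as plt

        rhos = sorted(self.table["rho"].unique())
        fig, axes = plt.subplots(len(rhos), len(effects),
                                 figsize=(3 * len(effects), 2.5 * len(rhos)),
                                 squeeze=False)
        for i, rho in enumerate(rhos):
            for j, eff in enumerate(effects):
                sub = self.table[(self.table["rho"] == rho) & (self.table["effect"] == eff)]
                ax = axes[i][j]
                ax.plot(sub["lam"], sub["mean"], "k--")
                ax.fill_between(sub["lam"], sub["lower"], sub["upper"], alpha=0.3)
                ax.axhline(0.0, color="gray", lw=0.5)
                ax.set_title(f"{eff}, rho={rho}")
                ax.set_xlabel("lambda")
        fig.tight_layout()
        return fig


def copula_mediator_pairs(coef_m, X, rho: float, K: int, seed):
    """Gaussian-copula potential mediator pairs (M0, M1), each (N, K).

    (Z0, Z1) are standard bivariate normal with correlation rho and each arm's
    mediator is the generalized-inverse-CDF transform of Phi(Z_a); rho = 1
    collapses to the comonotone coupling.
    """
    if not 0.0 <= rho <= 1.0:
        raise ValueError("rho must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return _mediator_pairs(rng, coef_m, X, K, rho)


def _logit_ry(r):
    if np.any(r <= 0.0) or np.any(r >= 1.0):
        warnings.warn("conditional mean r_y at the boundary; clamping", stacklevel=2)
    return logit(np.clip(r, _EPS, 1.0 - _EPS))


def sensitivity_average_effects(draws: PosteriorDraws, data: MediationDataset,
                                sens: SensitivityParams, K: int = 2,
                                seed: int = 0) -> MediationEffects:
    """Average mediation effects under the copula/logit-shift assumptions.

    At ``sens.lam == 0`` this reproduces :func:`zoibmed.effects.average_effects`
    called with the same seed and ``rho=sens.rho`` exactly, draw by draw.
    """
    curve = sensitivity_grid(draws, data, [sens.lam], [sens.rho], K=K, seed=seed,
                             _return_draws=True)
    df = curve.meta["draw_frames"][(sens.rho, sens.lam)]
    return MediationEffects(df, data.y_scale,
                            meta={"K": K, "seed": seed, "lam": sens.lam, "rho": sens.rho})


def sensitivity_grid(draws: PosteriorDraws, data: MediationDataset,
                     lambda_grid, rho_list, K: int = 2, seed: int = 0,
                     _return_draws: bool = False) -> SensitivityCurve:
    """Effect summaries over the Cartesian (lambda, rho) grid.

    Common random numbers: within each rho, the copula draws and bootstrap
    weights are shared across the whole lambda grid, so curves are smooth in
    lambda and tau is exactly invariant.
    """
    lambda_grid = list(lambda_grid)
    rho_list = list(rho_list)
    if not lambda_grid or not rho_list:
        raise ValueError("lambda_grid and rho_list must be nonempty")
    lo, hi = data.y_scale
    records = []
    draw_frames = {}
    for rho in rho_list:
        per_lam = {lam: np.empty((draws.B, 5)) for lam in lambda_grid}
        for b in range(draws.B):
            rng = np.random.default_rng([seed, b])  # same stream as average_effects
            omega = sample_bb_weights(data.n, rng).weights
            coef_m, coef_y = draws.coefficient_sets(b)
            m0, m1 = _mediator_pairs(rng, coef_m, data.X, K, rho)
            # conditional means r_y(M*(a'), a, X) for the four combos, computed
            # once per posterior draw, exactly as in the SI estimator
            rv = _ebar_rb(coef_y, data.X, m0, m1)
            rt = {k: _logit_ry(v) for k, v in rv.items()}
            dm = {(0, 1): m0 - m1, (1, 0): m1 - m0}
            for lam in lambda_grid:
                ebk = {}
                for a in (0, 1):
                    for ap in (0, 1):
                        if a == ap or lam == 0.0:
                            vals = rv[(a, ap)]  # shift term vanishes; keep r_y exactly
                        else:
                            vals = expit(rt[(a, ap)] + lam * dm[(a, ap)])
                        ebk[(a, ap)] = omega @ vals  # (K,)
                per_lam[lam][b] = _effects_from_ebar(ebk).mean(axis=1) * (hi - lo)
        for lam in lambda_grid:
            df = pd.DataFrame(per_lam[lam], columns=list(EFFECT_NAMES))
            draw_frames[(rho, lam)] = df
            for eff in EFFECT_NAMES:
                x = df[eff].to_numpy()
                records.append({
                    "rho": rho, "lam": lam, "effect": eff,
                    "mean": x.mean(), "sd": x.std(ddof=1) if len(x) > 1 else 0.0,
                    "lower": np.quantile(x, 0.025), "upper": np.quantile(x, 0.975),
                })
    curve = SensitivityCurve(pd.DataFrame(records), meta={"K": K, "seed": seed})
    if _return_draws:
        curve.meta["draw_frames"] = draw_frames
    return curve


def calibrate_lambda(data: MediationDataset, n_grid: int = 21,
                     min_halfwidth: float = 0.05) -> dict:
    """Pilot logit-link mean regression of Y on (X, A, M) for the lambda range.

    Fits E(Y | X, A, M) = expit(X b_X + a b_A + m b_M) by quasi-likelihood
    (binomial family with continuous response) and returns the mediator slope
    ``beta_hat_M`` together with an equally spaced grid of ``n_grid`` lambda
    values on [-2 |beta_hat_M|, +2 |beta_hat_M|], always containing 0.  The
    half-width is floored at ``min_halfwidth`` so a null pilot fit still yields
    a usable grid.
    """
    import statsmodels.api as sm

    Z = np.column_stack([data.X, data.A.astype(float), data.M])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(data.Y, Z, family=sm.families.Binomial())
        res = model.fit()
    if not np.all(np.isfinite(res.params)):
        raise RuntimeError(f"pilot quasi-likelihood fit failed: {res.params}")
    beta_m = float(res.params[-1])
    half = max(2.0 * abs(beta_m), min_halfwidth)
    if n_grid % 2 == 0:
        n_grid += 1  # keep 0 on the grid
    grid = np.linspace(-half, half, n_grid)
    grid[n_grid // 2] = 0.0
    return {"beta_hat_M": beta_m, "beta_hat_M_se": float(res.bse[-1]),
            "default_grid": grid}
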