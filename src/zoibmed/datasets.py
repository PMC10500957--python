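"""Packaged synthetic study conditions.

The simulation studies in this package are anchored to a *synthetic* base
coefficient set that plays the role of coefficients fitted to a real job-training
trial: the outcome (a bounded depression score) carries substantial mass at the
low boundary (no depression -> 0 after rescaling from a 1-5 scale) and mild mass
at the top; the mediator (a bounded self-efficacy score) carries mass at the
high boundary.  Treatment effects are small and beneficial: the program raises
self-efficacy slightly and lowers depression slightly.

Everything here is synthetic and versioned with the package; no external data
is required or downloaded.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import logit

from .design import CoefficientSet

__all__ = [
    "synthetic_covariate_pool",
    "synthetic_coefficients",
    "synthetic_trial",
]

#: original scale of both mediator and outcome in the synthetic study
SCALE = (1.0, 5.0)

#: design columns of the synthetic pool (intercept + standardized covariates)
POOL_COLUMNS = ["intercept", "depress_base", "econ_hard", "female"]


def synthetic_covariate_pool(n: int = 899, seed: int = 20230) -> np.ndarray:
    """Covariate pool (n, 4): intercept, two standardized numerics, one binary.

    ``depress_base`` (baseline depression) and ``econ_hard`` (economic
    hardship) are mildly correlated standard normals; ``female`` is Bernoulli
    with probability 0.55, entered as a raw 0/1 indicator.
    """
    rng = np.random.default_rng(seed)
    z = rng.standard_normal((n, 2))
    depress = z[:, 0]
    econ = 0.4 * z[:, 0] + np.sqrt(1 - 0.4**2) * z[:, 1]
    female = (rng.uniform(size=n) < 0.55).astype(float)
    return np.column_stack([np.ones(n), depress, econ, female])


def synthetic_coefficients() -> tuple[CoefficientSet, CoefficientSet]:
    """Synthetic base (mediator, outcome) coefficient sets (homogeneous model).

    Component order (alpha, gamma, mu, phi); columns follow POOL_COLUMNS.
    Treatment coefficients xi_hat: the program effect enters mainly the beta
    means (mu components), mediator xi_M = +0.12, outcome xi_Y = -0.10, with
    small boundary-probability effects.
    """
    # mediator: self-efficacy; almost no zeros, ~12% ones, right-leaning body
    med_beta = np.array([
        [logit(0.015), 0.30, 0.10, 0.10],   # alpha
        [logit(0.120), -0.40, -0.10, 0.20], # gamma
        [0.50, -0.25, -0.10, 0.05],         # mu  (logit scale)
        [np.log(8.0), 0.0, 0.0, 0.0],       # phi (log scale)
    ])
    med_treat = np.array([-0.10, 0.15, 0.12, 0.0])
    med = CoefficientSet("mediator", med_beta, med_treat)

    # outcome: depression; ~12% at the floor, ~1% at the ceiling, left-leaning
    out_beta = np.array([
        [logit(0.12), -0.60, -0.20, 0.10],  # alpha (floor = no depression)
        [logit(0.010), 0.40, 0.10, 0.0],    # gamma
        [-0.75, 0.50, 0.15, -0.05],         # mu
        [np.log(6.0), 0.0, 0.0, 0.0],       # phi
    ])
    out_treat = np.array([0.10, 0.0, -0.10, 0.0])
    # higher self-efficacy -> less depression, through all three location parts
    out_med = np.array([0.50, -0.30, -0.35, 0.0])
    out = CoefficientSet("outcome", out_beta, out_treat, out_med)
    return med, out


def misspecification_coefficients() -> tuple[CoefficientSet, CoefficientSet]:
    """Strong beta-part treatment effects with a saturating mediator response.

    The mediator's treatment coefficient acts only on the beta mean (logit
    shift +2) and the outcome's only on its beta mean (-0.5), with constant
    precision; the outcome responds strongly and nonlinearly to the mediator
    (large shifts in all three location components), so an unconstrained
    linear structural equation model is badly misspecified while the data
    remain a perfectly ordinary zero-one inflated sample.
    """
    base_m, base_y = synthetic_coefficients()
    med = CoefficientSet("mediator", base_m.beta.copy(),
                         np.array([0.0, 0.0, 2.0, 0.0]))
    out = CoefficientSet("outcome", base_y.beta.copy(),
                         np.array([0.0, 0.0, -0.5, 0.0]),
                         np.array([2.0, -1.0, -1.5, 0.0]))
    return med, out


def censored_linear_coefficients():
    """Censored-normal alternative mechanism: latent linear models.

    Returns (med_lin, out_lin, med_sd, out_sd) with med_lin over
    [POOL_COLUMNS, A] and out_lin over [POOL_COLUMNS, A, M]; latents are
    clamped to [0, 1] on observation.  Chosen so roughly a tenth of each
    response sits on a boundary.
    """
    med_lin = np.array([0.72, -0.05, -0.02, 0.02, 0.03])
    out_lin = np.array([0.45, 0.08, 0.03, -0.01, -0.02, -0.25])
    return med_lin, out_lin, 0.22, 0.20


def synthetic_trial(n: int = 899, seed: int = 0):
    """Convenience bundle: (coef_m, coef_y, covariate pool, scale).

    The pool is regenerated deterministically; ``seed`` only varies the pool.
    """
    coef_m, coef_y = synthetic_coefficients()
    pool = synthetic_covariate_pool(n, 20230 + seed)
    return coef_m, coef_y, pool, SCALE


def pool_frame(pool: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame(pool, columns=POOL_COLUMNS)
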