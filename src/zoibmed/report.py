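"""Posterior predictive checks and effect summary tables."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtr

from .design import MediationDataset, linear_predictors
from .effects import EFFECT_NAMES
from .inference import PosteriorDraws

__all__ = ["PPCReport", "ppc_replicates", "effects_table"]


@dataclass
class PPCReport:
    """Posterior predictive summaries vs their observed-data counterparts.

    ``boundary`` is tidy with columns (replicate, variable, arm, prop_zero,
    prop_one); ``observed_boundary`` matches without the replicate column.
    ``density`` holds kernel-density evaluations of the interior values on a
    fixed grid, per replicate/variable/arm; ``observed_density`` likewise.
    """

    boundary: pd.DataFrame
    observed_boundary: pd.DataFrame
    density: pd.DataFrame
    observed_density: pd.DataFrame
    grid: np.ndarray
    n_rep: int
    meta: dict = field(default_factory=dict)


def _boundary_props(v: np.ndarray, arm_mask: np.ndarray) -> tuple[float, float]:
    x = v[arm_mask]
    if len(x) == 0:
        return np.nan, np.nan
    return float(np.mean(x <= 1e-12)), float(np.mean(x >= 1 - 1e-12))


def _interior_kde(v: np.ndarray, arm_mask: np.ndarray, grid: np.ndarray) -> np.ndarray:
    x = v[arm_mask]
    x = x[(x > 1e-12) & (x < 1 - 1e-12)]
    if len(x) < 3 or np.std(x) == 0:
        return np.full(len(grid), np.nan)
    return stats.gaussian_kde(x)(grid)


def ppc_replicates(draws: PosteriorDraws, data: MediationDataset, n_rep: int = 100,
                   seed: int = 0, mode: str = "split", grid_size: int = 64) -> PPCReport:
    """Replicate datasets from the posterior predictive distribution.

    Each replicate uses one posterior coefficient draw (evenly spaced through
    the chain).  In the default ``mode='split'`` the mediator check regenerates
    M at the observed (A, X) while the outcome check conditions on the
    *observed* M (isolating the outcome-model fit); ``mode='joint'`` feeds the
    regenerated mediator into the outcome model.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    if mode not in ("split", "joint"):
        raise ValueError("mode must be 'split' or 'joint'")
    rng = np.random.default_rng(seed)
    grid = np.linspace(0.005, 0.995, grid_size)
    idx = np.linspace(0, draws.B - 1, n_rep).astype(int)
    b_rows, d_rows = [], []
    arms = {0: data.A == 0, 1: data.A == 1}
    for r, b in enumerate(idx):
        coef_m, coef_y = draws.coefficient_sets(int(b))
        pm = linear_predictors(coef_m, data.X, data.A)
        u0, u1 = rng.uniform(size=(2, data.n))
        m_rep = np.where(u0 < pm.alpha, 0.0,
                         np.where(u1 < pm.gamma, 1.0, rng.beta(pm.shape_a, pm.shape_b)))
        m_for_y = m_rep if mode == "joint" else data.M
        py = linear_predictors(coef_y, data.X, data.A, m_for_y)
        v0, v1 = rng.uniform(size=(2, data.n))
        y_rep = np.where(v0 < py.alpha, 0.0,
                         np.where(v1 < py.gamma, 1.0, rng.beta(py.shape_a, py.shape_b)))
        for var, v in (("Y", y_rep), ("M", m_rep)):
            for arm, mask in arms.items():
                p0, p1 = _boundary_props(v, mask)
                b_rows.append({"replicate": r, "variable": var, "arm": arm,
                               "prop_zero": p0, "prop_one": p1})
                kde = _interior_kde(v, mask, grid)
                d_rows.append({"replicate": r, "variable": var, "arm": arm,
                               **{f"g{j}": kde[j] for j in range(len(grid))}})
    ob_rows, od_rows = [], []
    for var, v in (("Y", data.Y), ("M", data.M)):
        for arm, mask in arms.items():
            p0, p1 = _boundary_props(v, mask)
            ob_rows.append({"variable": var, "arm": arm, "prop_zero": p0, "prop_one": p1})
            kde = _interior_kde(v, mask, grid)
            od_rows.append({"variable": var, "arm": arm,
                            **{f"g{j}": kde[j] for j in range(len(grid))}})
    return PPCReport(pd.DataFrame(b_rows), pd.DataFrame(ob_rows),
                     pd.DataFrame(d_rows), pd.DataFrame(od_rows), grid, n_rep,
                     meta={"mode": mode, "seed": seed})


def effects_table(effects) -> pd.DataFrame:
    """Posterior summary table: Est., SD, Lower, Upper, Z-score, P-value.

    Lower/Upper are the central 95% posterior interval; Z = mean / sd and the
    two-sided p-value 2 * Phi(-|Z|) follow the usual posterior-summary
    convention (not a frequentist test).  Degenerate draw sets (sd = 0) report
    an infinite Z and p = 0 with a warning.
    """
    df = effects.draws
    if len(df) < 2:
        raise ValueError("need at least 2 posterior draws to summarize")
    rows = []
    for eff in EFFECT_NAMES:
        x = df[eff].to_numpy()
        m, s = x.mean(), x.std(ddof=1)
        if x.max() == x.min():  # degenerate draw set (sd numerically meaningless)
            m, s = x[0], 0.0
            if m != 0:
                warnings.warn(f"degenerate posterior for {eff}: sd = 0", stacklevel=2)
            z = np.inf * np.sign(m) if m != 0 else 0.0
            p = 0.0 if m != 0 else 1.0
        else:
            z = m / s
            p = 2.0 * ndtr(-abs(z))
        rows.append({"Effect": eff, "Est.": m, "SD": s,
                     "Lower": np.quantile(x, 0.025), "Upper": np.quantile(x, 0.975),
                     "Z-score": z, "P-value": p})
    return pd.DataFrame(rows).set_index("Effect")
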