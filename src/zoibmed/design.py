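"""Data handling and the four-component ZOIB GLM design.

The analysis dataset holds a numeric design matrix X (intercept first, numeric
covariates centered/scaled, categoricals dummy-coded against the first-observed
level), a binary treatment A, and the mediator M and outcome Y rescaled from
their original bounded scale (e.g. 1-5) to [0, 1].

Each ZOIB response model has four generalized linear components with linear
predictors over (X, A) for the mediator and (X, A, M) for the outcome:

    logit(alpha) , logit(gamma) , logit(mu) , log(phi)

In the homogeneous model (the default) the treatment enters every component as
an additive coefficient; the heterogeneous model stores one full coefficient
vector per treatment arm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .zoib import ZoibParams

__all__ = [
    "COMPONENTS",
    "MediationDataset",
    "CoefficientSet",
    "ModelSpec",
    "rescale_to_unit",
    "effects_to_original_scale",
    "build_design",
    "linear_predictors",
]

COMPONENTS = ("alpha", "gamma", "mu", "phi")


def rescale_to_unit(v, lo: float, hi: float):
    """Map values from the original scale [lo, hi] to [0, 1]."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    v = np.asarray(v, dtype=float)
    if np.any((v < lo) | (v > hi)):
        bad = np.flatnonzero((v < lo) | (v > hi))
        raise ValueError(f"values outside [{lo}, {hi}] at records {bad[:10].tolist()}")
    return (v - lo) / (hi - lo)


def effects_to_original_scale(effect, lo: float, hi: float):
    """Scale a [0,1]-scale effect (a difference) back to the original units."""
    if not lo < hi:
        raise ValueError("require lo < hi")
    return np.asarray(effect, dtype=float) * (hi - lo)


@dataclass
class MediationDataset:
    """Subject-level analysis data after encoding and rescaling."""

    X: np.ndarray  # (N, p) design incl. leading intercept column
    A: np.ndarray  # (N,) binary treatment
    M: np.ndarray  # (N,) mediator in [0, 1]
    Y: np.ndarray  # (N,) outcome in [0, 1]
    m_scale: tuple = (0.0, 1.0)
    y_scale: tuple = (0.0, 1.0)
    colnames: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.A = np.asarray(self.A)
        self.M = np.asarray(self.M, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float)
        n = self.X.shape[0]
        if not (len(self.A) == len(self.M) == len(self.Y) == n):
            raise ValueError("X, A, M, Y must have matching length")
        if n < 1:
            raise ValueError("dataset must contain at least one record")
        if not np.all(np.isin(self.A, (0, 1))):
            raise ValueError("treatment A must be binary 0/1")
        for name, v in (("M", self.M), ("Y", self.Y)):
            if np.any(np.isnan(v)):
                raise ValueError(f"missing values in {name}; impute before analysis")
            if np.any((v < 0) | (v > 1)):
                raise ValueError(f"{name} must lie in [0, 1] after rescaling")
        if not self.colnames:
            self.colnames = [f"x{j}" for j in range(self.X.shape[1])]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class ModelSpec:
    """Column roles and scale bounds for building a MediationDataset."""

    treatment: str
    mediator: str
    outcome: str
    covariates: list
    categorical: list = field(default_factory=list)
    mediator_range: tuple = (0.0, 1.0)
    outcome_range: tuple = (0.0, 1.0)
    homogeneous: bool = True


def build_design(raw: pd.DataFrame, spec: ModelSpec) -> MediationDataset:
    """Encode a raw subject-level table into an analysis-ready dataset.

    Numeric covariates are centered and scaled to sd 1 (the standardization
    statistics are frozen in ``meta`` so downstream prediction and simulation
    reuse them); categoricals are dummy-coded with the first-observed level as
    reference; the intercept column is prepended unscaled.
    """
    cols, names = [np.ones(len(raw))], ["intercept"]
    meta = {"standardize": {}, "levels": {}}
    for c in spec.covariates:
        if c not in raw.columns:
            raise KeyError(f"covariate column '{c}' not found")
        if c in spec.categorical or raw[c].dtype == object:
            levels = list(pd.unique(raw[c]))
            meta["levels"][c] = levels
            for lev in levels[1:]:
                cols.append((raw[c] == lev).to_numpy(dtype=float))
                names.append(f"{c}[{lev}]")
        else:
            v = raw[c].to_numpy(dtype=float)
            sd = v.std(ddof=0)
            if sd == 0:
                warnings.warn(f"constant covariate '{c}' dropped", stacklevel=2)
                continue
            meta["standardize"][c] = (float(v.mean()), float(sd))
            cols.append((v - v.mean()) / sd)
            names.append(c)
    X = np.column_stack(cols)
    mlo, mhi = spec.mediator_range
    ylo, yhi = spec.outcome_range
    return MediationDataset(
        X=X,
        A=raw[spec.treatment].to_numpy(),
        M=rescale_to_unit(raw[spec.mediator].to_numpy(dtype=float), mlo, mhi),
        Y=rescale_to_unit(raw[spec.outcome].to_numpy(dtype=float), ylo, yhi),
        m_scale=(float(mlo), float(mhi)),
        y_scale=(float(ylo), float(yhi)),
        colnames=names,
        meta=meta,
    )


@dataclass
class CoefficientSet:
    """Coefficients of the four ZOIB GLM components for one response.

    Homogeneous mode: ``beta`` is (4, p) over the design columns, ``treat`` is
    (4,) additive treatment coefficients, ``med`` is (4,) mediator coefficients
    (outcome model only, else None).  Heterogeneous mode: ``beta`` is (2, 4, p)
    with one full vector per treatment arm and ``med`` is (2, 4); ``treat`` is
    None (arm differences live in the per-arm vectors).

    Component order follows :data:`COMPONENTS` = (alpha, gamma, mu, phi).
    """

    response: str  # "mediator" | "outcome"
    beta: np.ndarray
    treat: np.ndarray | None = None
    med: np.ndarray | None = None
    homogeneous: bool = True

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.treat is not None:
            self.treat = np.asarray(self.treat, dtype=float)
        if self.med is not None:
            self.med = np.asarray(self.med, dtype=float)
        if self.response not in ("mediator", "outcome"):
            raise ValueError("response must be 'mediator' or 'outcome'")
        if self.homogeneous:
            if self.beta.shape[0] != 4 or self.beta.ndim != 2:
                raise ValueError("homogeneous beta must have shape (4, p)")
            if self.treat is None or self.treat.shape != (4,):
                raise ValueError("homogeneous model requires treat of shape (4,)")
            if self.response == "outcome" and (self.med is None or self.med.shape != (4,)):
                raise ValueError("outcome model requires med of shape (4,)")
        else:
            if self.beta.ndim != 3 or self.beta.shape[:2] != (2, 4):
                raise ValueError("heterogeneous beta must have shape (2, 4, p)")
            if self.response == "outcome" and (self.med is None or self.med.shape != (2, 4)):
                raise ValueError("outcome model requires med of shape (2, 4)")

    @property
    def p(self) -> int:
        return self.beta.shape[-1]

    def replace_treat(self, new_treat: np.ndarray) -> "CoefficientSet":
        if not self.homogeneous:
            raise ValueError("treatment override is defined for the homogeneous model")
        return CoefficientSet(self.response, self.beta.copy(), np.asarray(new_treat, float),
                              None if self.med is None else self.med.copy(), True)


def linear_predictors(coeffs: CoefficientSet, X, a, m=None) -> ZoibParams:
    """Evaluate the four GLM components at covariates X, treatment a, mediator m.

    ``X`` is (n, p) (or a single row), ``a`` a scalar or (n,) array in {0, 1},
    ``m`` required iff ``coeffs.response == 'outcome'``.  ``m`` may carry extra
    trailing axes (e.g. Monte-Carlo replicates shaped (n, K)); the returned
    parameter arrays broadcast accordingly.

    alpha, gamma, mu come through the inverse logit, phi through exp.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if (m is None) != (coeffs.response == "mediator"):
        raise ValueError("mediator value m must be supplied iff outcome model")
    if X.shape[1] != coeffs.p:
        raise ValueError(f"design width {X.shape[1]} != coefficient length {coeffs.p}")
    a = np.asarray(a)
    if coeffs.homogeneous:
        eta = X @ coeffs.beta.T  # (n, 4)
        eta = eta + np.multiply.outer(np.broadcast_to(a, (X.shape[0],)).astype(float),
                                      coeffs.treat)
    else:
        eta_arm = np.stack([X @ coeffs.beta[0].T, X @ coeffs.beta[1].T])  # (2, n, 4)
        sel = np.broadcast_to(a, (X.shape[0],)).astype(int)
        eta = eta_arm[sel, np.arange(X.shape[0]), :]
    if m is not None:
        m = np.asarray(m, dtype=float)
        if coeffs.homogeneous:
            med = coeffs.med
        else:
            sel = np.broadcast_to(a, (X.shape[0],)).astype(int)
            med = coeffs.med[sel]  # (n, 4)
        if m.ndim > 1:
            # broadcast replicates: eta (n, 4) -> (n, ..., 4), m (n, K)
            eta = eta[:, None, :] + m[..., None] * (med if med.ndim == 1 else med[:, None, :])
        else:
            eta = eta + m[:, None] * med
    e = np.moveaxis(eta, -1, 0)  # (4, ...)
    return ZoibParams(expit(e[0]), expit(e[1]), expit(e[2]), np.exp(e[3]))
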