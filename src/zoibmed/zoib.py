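"""Zero-one inflated beta (ZOIB) distribution.

A ZOIB(alpha, gamma, mu, phi) random variable Z lives on [0, 1] and mixes two
point masses with a beta density:

    Pr(Z = 0)              = alpha
    Pr(Z = 1 | Z != 0)     = gamma
    [Z | Z not in {0, 1}]  ~ Beta(mu * phi, (1 - mu) * phi)

so that ``mu`` is the conditional mean of the continuous part and ``phi`` its
precision.  The mean is ``(1 - alpha) * gamma + (1 - alpha) * (1 - gamma) * mu``.

All functions broadcast over numpy arrays in both the evaluation points and the
parameters, which is what the Monte-Carlo g-formula machinery relies on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

__all__ = [
    "ZoibParams",
    "zoib_logpdf",
    "zoib_mean",
    "zoib_cdf",
    "zoib_quantile",
    "zoib_rng",
]

# values within this distance of 0/1 are treated as boundary atoms; inputs read
# from files may carry float noise
ATOM_TOL = 1e-12


@dataclass(frozen=True)
class ZoibParams:
    """Parameters of a ZOIB distribution (scalars or broadcastable arrays).

    alpha : probability of the value 0, in [0, 1]
    gamma : probability of 1 given nonzero, in [0, 1]
    mu    : mean of the beta component, strictly inside (0, 1)
    phi   : beta precision, strictly positive
    """

    alpha: np.ndarray
    gamma: np.ndarray
    mu: np.ndarray
    phi: np.ndarray

    def __post_init__(self) -> None:
        for name in ("alpha", "gamma", "mu", "phi"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))

    def validate(self) -> "ZoibParams":
        a, g, mu, phi = self.alpha, self.gamma, self.mu, self.phi
        if np.any((a < 0) | (a > 1)):
            raise ValueError("alpha must lie in [0, 1]")
        if np.any((g < 0) | (g > 1)):
            raise ValueError("gamma must lie in [0, 1]")
        if np.any((mu <= 0) | (mu >= 1)):
            raise ValueError("mu must lie strictly inside (0, 1)")
        if np.any(phi <= 0):
            raise ValueError("phi must be strictly positive")
        return self

    @property
    def shape_a(self) -> np.ndarray:
        """First beta shape parameter mu * phi."""
        return self.mu * self.phi

    @property
    def shape_b(self) -> np.ndarray:
        """Second beta shape parameter (1 - mu) * phi."""
        return (1.0 - self.mu) * self.phi


def _check_unit(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError(f"{name} must lie in [0, 1]")
    return x


def zoib_logpdf(z, params: ZoibParams):
    """Log density/mass of the ZOIB distribution.

    Returns log(alpha) at z == 0, log((1-alpha) * gamma) at z == 1, and the
    beta log density plus log((1-alpha) * (1-gamma)) on the interior.  Boundary
    probabilities of exactly zero yield -inf rather than raising, so samplers
    can reject such parameter values gracefully.
    """
    z = _check_unit(z, "z")
    params.validate()
    a, g = params.alpha, params.gamma
    with np.errstate(divide="ignore"):
        log_a = np.log(a)
        log_one = np.log1p(-a) + np.log(g)
        log_int = np.log1p(-a) + np.log1p(-g)
    is0 = z <= ATOM_TOL
    is1 = z >= 1.0 - ATOM_TOL
    # clip interior evaluation points away from the boundary; at the atoms the
    # beta term is discarded below anyway
    z_in = np.clip(z, 1e-300, 1.0 - 1e-16)
    beta_ld = stats.beta.logpdf(z_in, params.shape_a, params.shape_b)
    out = np.where(is0, log_a, np.where(is1, log_one, log_int + beta_ld))
    return out[()] if np.isscalar(z) or out.ndim == 0 else out


def zoib_mean(params: ZoibParams):
    """Expected value (1 - alpha) * gamma + (1 - alpha) * (1 - gamma) * mu."""
    a, g, mu = params.alpha, params.gamma, params.mu
    return (1.0 - a) * (g + (1.0 - g) * mu)


def zoib_cdf(z, params: ZoibParams):
    """CDF F(z) = alpha + (1-alpha)(1-gamma) * I_z(mu*phi, (1-mu)*phi) on [0, 1).

    Right-continuous, with F(1) = 1 (the jump at 1 has mass (1-alpha)*gamma).
    """
    z = _check_unit(z, "z")
    params.validate()
    a, g = params.alpha, params.gamma
    z_in = np.clip(z, 0.0, 1.0)
    inc = special.betainc(params.shape_a, params.shape_b, z_in)
    cdf = a + (1.0 - a) * (1.0 - g) * inc
    cdf = np.where(z >= 1.0 - ATOM_TOL, 1.0, cdf)
    return cdf[()] if np.isscalar(z) or np.ndim(cdf) == 0 else cdf


def zoib_quantile(u, params: ZoibParams):
    """Generalized inverse CDF, F^-(u) = inf{z : F(z) >= u}.

    Returns 0 inside the zero atom (u <= alpha), 1 beyond the interior mass,
    and the rescaled beta quantile in between.
    """
    u = _check_unit(u, "u")
    params.validate()
    a, g = params.alpha, params.gamma
    p_int = (1.0 - a) * (1.0 - g)  # mass of the continuous segment
    upper = a + p_int
    interior = (u > a) & (u <= upper)
    if np.ndim(u) == 0 and np.ndim(interior) == 0:
        if not interior:
            return 0.0 if u <= np.asarray(a)[()] else 1.0
        u_beta = (u - a) / p_int
        return special.betaincinv(params.shape_a, params.shape_b, u_beta)[()]
    # invert only where the draw lands in the continuous segment
    ub, ab, pb = np.broadcast_arrays(u, a, p_int)
    sa = np.broadcast_to(params.shape_a, ub.shape)
    sb = np.broadcast_to(params.shape_b, ub.shape)
    out = np.where(ub <= ab, 0.0, 1.0)
    idx = np.broadcast_to(interior, ub.shape)
    u_beta = np.clip((ub[idx] - ab[idx]) / pb[idx], 0.0, 1.0)
    out[idx] = special.betaincinv(sa[idx], sb[idx], u_beta)
    return out


def zoib_rng(params: ZoibParams, n: int, seed) -> np.ndarray:
    """Draw ``n`` i.i.d. ZOIB variates.

    Equivalent in distribution to the probability integral transform
    ``zoib_quantile(U)`` with U ~ Uniform(0, 1), but samples the mixture
    components directly.  ``seed`` may be an int or a numpy Generator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    params.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    a = np.broadcast_to(params.alpha, (n,))
    g = np.broadcast_to(params.gamma, (n,))
    sa = np.broadcast_to(params.shape_a, (n,))
    sb = np.broadcast_to(params.shape_b, (n,))
    u0 = rng.uniform(size=n)
    u1 = rng.uniform(size=n)
    body = rng.beta(sa, sb)
    out = np.where(u0 < a, 0.0, np.where(u1 < g, 1.0, body))
    return out
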