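"""Independent deterministic oracles for the Monte-Carlo g-formula estimators.

These never touch the estimator code paths: counterfactual means come from
adaptive quadrature over the mediator law composed with the conditional
outcome mean, and the sensitivity functional from 2-D Gauss-Hermite quadrature
over the Gaussian copula.
"""

import numpy as np
from scipy import integrate, stats
from scipy.special import expit, logit, ndtr

from zoibmed.design import linear_predictors
from zoibmed.zoib import ZoibParams, zoib_mean, zoib_quantile


def _mediator_params(cm, x_row, a):
    return linear_predictors(cm, x_row[None, :], a)


def _ry(cy, x_row, a, m):
    """Conditional outcome mean r_y(m, a, x) for scalar m."""
    p = linear_predictors(cy, x_row[None, :], a, np.array([m]))
    return float(zoib_mean(p)[0])


def mean_potential_outcome(cm, cy, x_row, a, ap):
    """E[Y{a, M(a')} | X = x] by adaptive quadrature over the mediator law."""
    pm = _mediator_params(cm, x_row, ap)
    alpha = float(pm.alpha[0])
    gamma = float(pm.gamma[0])
    sa, sb = float(pm.shape_a[0]), float(pm.shape_b[0])
    val = alpha * _ry(cy, x_row, a, 0.0)
    val += (1 - alpha) * gamma * _ry(cy, x_row, a, 1.0)
    body, _ = integrate.quad(
        lambda m: stats.beta.pdf(m, sa, sb) * _ry(cy, x_row, a, m), 0.0, 1.0,
        limit=200)
    val += (1 - alpha) * (1 - gamma) * body
    return val


def mean_effects(cm, cy, x_rows, weights=None):
    """The five average mediation effects by quadrature, averaged over x_rows."""
    x_rows = np.atleast_2d(x_rows)
    w = np.full(len(x_rows), 1.0 / len(x_rows)) if weights is None else weights
    eb = {}
    for a in (0, 1):
        for ap in (0, 1):
            eb[(a, ap)] = sum(wi * mean_potential_outcome(cm, cy, x, a, ap)
                              for wi, x in zip(w, x_rows))
    return np.array([eb[(0, 1)] - eb[(0, 0)], eb[(1, 1)] - eb[(1, 0)],
                     eb[(1, 0)] - eb[(0, 0)], eb[(1, 1)] - eb[(0, 1)],
                     eb[(1, 1)] - eb[(0, 0)]])


def sensitivity_potential_outcome(cm, cy, x_row, a, ap, lam, rho, n_leg=120):
    """Copula/logit-shift counterfactual mean by nested piecewise quadrature.

    E[Y{a, M(a')}] = E over (z_a, z_a') bivariate normal(rho) of
    expit( logit r_y(m', a, x) + lam * (m - m') ), with m = F^-(Phi(z_a) | a)
    and m' = F^-(Phi(z_a') | a').  The mediator atoms are handled in closed
    form (conditional normal tail masses) and only the smooth interior pieces
    are integrated with Gauss-Legendre, so the result converges fast despite
    the discontinuous probability-integral transform.
    """
    from scipy.stats import norm

    if a == ap:
        # z_a and z_a' coincide, the shift vanishes, and the quantity reduces
        # to the ordinary conditional-mean integral under the mediator law
        return mean_potential_outcome(cm, cy, x_row, a, ap)

    pm_a = _mediator_params(cm, x_row, a)
    pm_ap = _mediator_params(cm, x_row, ap)

    def thresholds(pm):
        alpha = float(pm.alpha[0])
        gamma = float(pm.gamma[0])
        upper = alpha + (1 - alpha) * (1 - gamma)
        return norm.ppf(alpha), norm.ppf(upper)

    t0a, t1a = thresholds(pm_a)
    t0p, t1p = thresholds(pm_ap)
    sd_c = np.sqrt(max(1e-300, 1.0 - rho**2))

    # inner arm-a mediator nodes on the continuous segment (fixed in z space)
    gl_x, gl_w = np.polynomial.legendre.leggauss(n_leg)
    za_n = 0.5 * (t1a - t0a) * gl_x + 0.5 * (t1a + t0a)
    za_w = 0.5 * (t1a - t0a) * gl_w
    m_n = zoib_quantile(ndtr(za_n), ZoibParams(pm_a.alpha, pm_a.gamma,
                                               pm_a.mu, pm_a.phi))

    def inner(c, zp):
        """E[expit(c + lam * m) | z_ap = zp], vectorized over zp."""
        mu_c = rho * np.asarray(zp)
        p0 = ndtr((t0a - mu_c) / sd_c)
        p1 = 1.0 - ndtr((t1a - mu_c) / sd_c)
        val = p0 * expit(c) + p1 * expit(c + lam)
        dens = norm.pdf((za_n[None, :] - mu_c[:, None]) / sd_c) / sd_c
        val = val + (za_w[None, :] * expit(c[:, None] + lam * m_n[None, :])
                     * dens).sum(axis=1)
        return val

    def c_of_mp(mp):
        ry = zoib_mean(linear_predictors(
            cy, np.repeat(x_row[None, :], len(np.atleast_1d(mp)), axis=0),
            a, np.atleast_1d(mp)))
        return logit(np.clip(ry, 1e-12, 1 - 1e-12)) - lam * np.atleast_1d(mp)

    total = 0.0
    # outer atom segments: m' fixed at 0 or 1, integrate the inner expectation
    # against the standard normal law of z_ap over the corresponding tail
    for (lo, hi, mp_fix) in ((-np.inf, t0p, 0.0), (t1p, np.inf, 1.0)):
        u_lo, u_hi = ndtr(lo) if np.isfinite(lo) else 0.0, \
            ndtr(hi) if np.isfinite(hi) else 1.0
        if u_hi - u_lo < 1e-14:
            continue
        u_n = 0.5 * (u_hi - u_lo) * gl_x + 0.5 * (u_hi + u_lo)
        u_w = 0.5 * (u_hi - u_lo) * gl_w
        zp = norm.ppf(u_n)
        c = c_of_mp(np.full(len(zp), mp_fix))
        total += float(np.sum(u_w * inner(c, zp)))
    # outer continuous segment: m' = F^-(Phi(z_ap)) on (t0p, t1p)
    u_lo, u_hi = ndtr(t0p), ndtr(t1p)
    if u_hi - u_lo > 1e-14:
        u_n = 0.5 * (u_hi - u_lo) * gl_x + 0.5 * (u_hi + u_lo)
        u_w = 0.5 * (u_hi - u_lo) * gl_w
        zp = norm.ppf(u_n)
        mp = zoib_quantile(u_n, ZoibParams(pm_ap.alpha, pm_ap.gamma,
                                           pm_ap.mu, pm_ap.phi))
        c = c_of_mp(mp)
        total += float(np.sum(u_w * inner(c, zp)))
    return total


def sensitivity_effects(cm, cy, x_rows, lam, rho, weights=None, n_leg=120):
    x_rows = np.atleast_2d(x_rows)
    w = np.full(len(x_rows), 1.0 / len(x_rows)) if weights is None else weights
    eb = {}
    for a in (0, 1):
        for ap in (0, 1):
            eb[(a, ap)] = sum(
                wi * sensitivity_potential_outcome(cm, cy, x, a, ap, lam, rho, n_leg)
                for wi, x in zip(w, x_rows))
    return np.array([eb[(0, 1)] - eb[(0, 0)], eb[(1, 1)] - eb[(1, 0)],
                     eb[(1, 0)] - eb[(0, 0)], eb[(1, 1)] - eb[(0, 1)],
                     eb[(1, 1)] - eb[(0, 0)]])


def brute_force_quantile_effects(cm, cy, x_rows, q, n_sim, seed):
    """Quantile effects from independent (non-comonotone) large-sample draws."""
    rng = np.random.default_rng(seed)
    x_rows = np.atleast_2d(x_rows)
    idx = rng.integers(0, len(x_rows), n_sim)
    X = x_rows[idx]
    qs = {}
    for a in (0, 1):
        for ap in (0, 1):
            pm = linear_predictors(cm, X, ap)
            m = zoib_quantile(rng.uniform(size=n_sim), pm)
            py = linear_predictors(cy, X, a, m)
            y = zoib_quantile(rng.uniform(size=n_sim), py)
            qs[(a, ap)] = np.quantile(y, q)
    return np.array([qs[(0, 1)] - qs[(0, 0)], qs[(1, 1)] - qs[(1, 0)],
                     qs[(1, 0)] - qs[(0, 0)], qs[(1, 1)] - qs[(0, 1)],
                     qs[(1, 1)] - qs[(0, 0)]])
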