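import numpy as np
import pytest

from zoibmed import MCMCConfig, datasets, fit_posterior
from zoibmed.design import CoefficientSet, MediationDataset
from zoibmed.inference import PosteriorDraws
from zoibmed.simulate import generate_zoib_dataset

# small-but-realistic sampler budget used throughout the test suite
SIM_CFG = dict(chains=4, iterations=250, warmup=125)


def draws_from_coeffs(pairs, colnames=None):
    """Build a PosteriorDraws object from explicit (mediator, outcome) pairs.

    Useful for oracle comparisons where the "posterior" is a handful of known
    coefficient sets rather than a fitted object.
    """
    B = len(pairs)
    p = pairs[0][0].p
    med_beta = np.stack([cm.beta for cm, _ in pairs])
    med_treat = np.stack([cm.treat for cm, _ in pairs])
    out_beta = np.stack([cy.beta for _, cy in pairs])
    out_treat = np.stack([cy.treat for _, cy in pairs])
    out_med = np.stack([cy.med for _, cy in pairs])
    return PosteriorDraws(med_beta, med_treat, out_beta, out_treat, out_med,
                          chain=np.zeros(B, dtype=int), draw=np.arange(B),
                          colnames=colnames or [f"x{j}" for j in range(p)])


def intercept_only_pair(med_params=(-2.0, -1.0, 0.3, 2.0, 0.5),
                        out_params=(-1.5, -2.5, -0.4, 1.8),
                        med_treat=(0.2, 0.3, 0.4, 0.0),
                        out_treat=(0.1, 0.0, -0.3, 0.0),
                        out_med=(0.8, -0.5, -0.9, 0.0)):
    """Intercept-only mediator/outcome coefficient sets (single design column).

    ``med_params`` = (alpha0, gamma0, mu0, logphi0, spare); ``out_params``
    likewise for the outcome intercepts.
    """
    cm = CoefficientSet("mediator",
                        np.array([[med_params[0]], [med_params[1]],
                                  [med_params[2]], [med_params[3]]]),
                        np.asarray(med_treat, float))
    cy = CoefficientSet("outcome",
                        np.array([[out_params[0]], [out_params[1]],
                                  [out_params[2]], [out_params[3]]]),
                        np.asarray(out_treat, float), np.asarray(out_med, float))
    return cm, cy


@pytest.fixture(scope="session")
def synth_trial():
    return datasets.synthetic_trial(899)


@pytest.fixture(scope="session")
def synth_data(synth_trial):
    coef_m, coef_y, pool, scale = synth_trial
    return generate_zoib_dataset(coef_m, coef_y, pool, 899, 1, scale)


@pytest.fixture(scope="session")
def fitted_draws(synth_data):
    return fit_posterior(synth_data, mcmc=MCMCConfig(seed=3, **SIM_CFG))


@pytest.fixture()
def toy_data():
    """Intercept-only dataset: design is a single constant column."""
    n = 40
    rng = np.random.default_rng(5)
    return MediationDataset(X=np.ones((n, 1)), A=rng.integers(0, 2, n),
                            M=rng.uniform(0.1, 0.9, n), Y=rng.uniform(0.1, 0.9, n),
                            m_scale=(0.0, 1.0), y_scale=(0.0, 1.0))
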