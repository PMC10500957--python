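"""Quantile mediation effects.

Average effects can hide what happens in the tails of a skewed, boundary-
inflated outcome.  Quantile effects compare the q-th quantile of the
counterfactual outcome distributions (population-level quantile contrasts;
the decomposition tau_q = delta_q(1) + zeta_q(0) holds by construction).
"""

from zoibmed import MCMCConfig, datasets, fit_posterior, quantile_effects
from zoibmed.simulate import generate_zoib_dataset

coef_m, coef_y, pool, scale = datasets.synthetic_trial(899)
data = generate_zoib_dataset(coef_m, coef_y, pool, n=899, seed=1, scale=scale)
draws = fit_posterior(data, mcmc=MCMCConfig(chains=4, iterations=500,
                                            warmup=250, seed=1))

for q in (0.25, 0.5, 0.75):
    eff = quantile_effects(draws.thin(200), data, K=10, q=q, seed=2)
    tab = eff.summary()
    print(f"q = {q}: tau_q = {tab.loc['tau', 'Est.']:+.4f} "
          f"[{tab.loc['tau', 'Lower']:+.4f}, {tab.loc['tau', 'Upper']:+.4f}]")
# the median-effect row answers: how much does the program move the median
# depression score of the whole population?
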