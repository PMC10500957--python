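"""Sensitivity of mediation effects to unmeasured mediator-outcome confounding.

Sequential ignorability cannot be tested from data.  The sensitivity analysis
replaces it with two weaker assumptions indexed by pure (unidentified)
parameters: a Gaussian-copula correlation rho between the two potential
mediators, and a logit-scale shift lambda capturing residual confounding.
lambda = 0 reproduces the sequential-ignorability answer exactly; the lambda
range is calibrated from a pilot logit-link regression of the outcome on
(X, A, M): |lambda| at most twice the pilot mediator slope.
"""

import numpy as np

from zoibmed import MCMCConfig, calibrate_lambda, datasets, fit_posterior, \
    sensitivity_grid
from zoibmed.simulate import generate_zoib_dataset

coef_m, coef_y, pool, scale = datasets.synthetic_trial(899)
data = generate_zoib_dataset(coef_m, coef_y, pool, n=899, seed=1, scale=scale)
draws = fit_posterior(data, mcmc=MCMCConfig(chains=4, iterations=500,
                                            warmup=250, seed=1)).thin(300)

cal = calibrate_lambda(data, n_grid=9)
print(f"pilot mediator slope {cal['beta_hat_M']:+.3f} -> lambda grid "
      f"[{cal['default_grid'][0]:+.3f}, {cal['default_grid'][-1]:+.3f}]")

curve = sensitivity_grid(draws, data, cal["default_grid"], rho_list=[0.0, 0.5, 0.95],
                         K=2, seed=2)
sub = curve.table.query("effect == 'delta0' and rho == 0.95").sort_values("lam")
print("\nNIE delta(0) vs lambda at rho = 0.95:")
for _, row in sub.iterrows():
    print(f"  lambda {row['lam']:+.3f}: {row['mean']:+.4f} "
          f"[{row['lower']:+.4f}, {row['upper']:+.4f}]")

tau = curve.table.query("effect == 'tau' and rho == 0.95")["mean"]
print(f"\ntau range over the lambda grid: {tau.max() - tau.min():.2e} "
      "(exactly invariant: the total effect never depends on lambda)")
# curve.plot() draws the posterior-mean line and 95% band per effect and rho
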