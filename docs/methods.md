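# Methods

## Observed-data model

Both responses are rescaled to [0, 1] from their original bounded scale
(`(z − lo)/(hi − lo)`; values exactly on a bound map to the atoms, interior
values never do; inputs within 1e−12 of an atom are treated as boundary to
absorb file-I/O float noise).  Each response follows a zero-one inflated beta
(ZOIB) law with four GLM components:

| component | link  | meaning                                  |
|-----------|-------|------------------------------------------|
| α         | logit | probability of the value 0               |
| γ         | logit | probability of 1 given nonzero           |
| μ         | logit | mean of the interior beta density        |
| φ         | log   | precision of the interior beta density   |

Linear predictors are `X'β + θ·A` for the mediator and `X'β + θ·A + η·M` for
the outcome (homogeneous model: treatment enters additively in every
component).  Numeric covariates are centered and scaled to unit sd — the
statistics are frozen at build time and reused for all downstream prediction
and simulation — and categoricals are dummy-coded against the first-observed
level.  Coefficients get iid Normal(0, τ²) priors with τ = 10 by default on
the standardized design; this is effectively flat for every block yet keeps
the posterior proper when a boundary category is rare or absent.  A
heterogeneous variant (one full coefficient vector per treatment arm) is
supported by the coefficient containers and the prediction/simulation path;
model fitting targets the homogeneous model, which is also the default
analysis model.

The covariate distribution F_X is given a Bayesian-bootstrap prior: discrete
support on the observed rows with flat-Dirichlet posterior weights ω, sampled
exactly.

## Posterior computation

The ZOIB likelihood factorizes exactly into three independent blocks per
response: a Bernoulli GLM on the zero indicator (α), a Bernoulli GLM on the
one-given-nonzero indicator (γ), and a beta GLM on the interior values with
(μ, φ) sampled jointly.  Outcome and mediator models have disjoint
parameters, so fitting them blockwise is identical in distribution to a joint
fit and yields one diagnostic pass.

Each block posterior is smooth and log-concave, and its MAP/Laplace
approximation (L-BFGS with analytic gradients; numerical Hessian from
gradient differences) is accurate to a few percent.  Sampling therefore uses
**sampling-importance-resampling**: per "chain", an independent batch of
multivariate-t proposals (df 5, scale 1.5 × the Laplace Cholesky factor,
inflated 1.5× and retried when the importance-weight effective sample size
drops below 2% of the proposals) is weighted by the exact block log posterior
and resampled to the requested draw count.  Four proposals per retained draw
(minimum 1000 per chain) are used by default.  This choice was validated two
ways on representative blocks: the posterior sd agrees with statsmodels'
logistic MLE asymptotics to three digits, and weight diagnostics show ESS in
the tens of thousands.  In repeated-sampling calibration runs (the parameter-
recovery acceptance test) the 95% credible intervals cover the generating
coefficients at the nominal rate and the posterior CDF of the truth is
uniform (Kolmogorov-Smirnov p ≈ 0.6).  An ensemble MCMC engine was evaluated
first and rejected: at any affordable budget its draws were systematically
~15% under-dispersed on these blocks, which showed up directly as ~92%
interval coverage.

Because chains are independent importance-sampling batches, split-R-hat and
bulk ESS (via arviz) genuinely measure sampling adequacy; per-block
importance-weight ESS is reported alongside.  Blocks with no data (e.g. a
mediator with no interior values) fall back to exact prior sampling, so
degenerate datasets still produce draws.  All samplers are seeded; identical
configuration means bit-identical draws.

`MCMCConfig(chains, iterations, warmup, seed)` keeps the familiar MCMC
interface: `chains × (iterations − warmup)` is the number of retained draws
(default 4 × 1000).

## Effect computation

Per posterior draw b: draw ω ~ Dirichlet(1,…,1); draw base normals
(E0, E1) of shape (N, K); set the potential mediators through the
probability-integral transform of the generalized inverse CDF,
`M*(a) = F_M⁻(Φ(Z_a) | a, X)` with Z0 = E0 and Z1 = ρE0 + √(1−ρ²)E1.  The
default coupling is comonotone (ρ = 1, a single shared uniform), which does
not change any marginal quantity but minimizes Monte-Carlo noise in the
contrasts.

*Average effects* are Rao-Blackwellized: the simulated outcome is replaced by
its conditional ZOIB mean r_y(M*(a′), a, X), and
Ē(a, a′) = K⁻¹ Σ_{i,k} ω_i r_y(M*_{ik}(a′), a, X_i).  The five effects are
differences of the four Ē values, so δ(1) + ζ(0) = δ(0) + ζ(1) = τ holds to
machine precision per draw.  K = 2 suffices (the per-draw Monte-Carlo
standard error — between-replicate variance / K, square-rooted — is reported
so users can verify it is far below the posterior sd).  A raw simulated-
outcome mode exists for variance comparisons.

*Quantile effects* cannot be Rao-Blackwellized; they use a second comonotone
uniform V for the outcome and form four ω-weighted empirical distributions
with atoms of weight ω_i/K (K = 10 by default).  The weighted quantile is the
left-continuous generalized inverse of the weighted ECDF.  Building the
weighted mixture directly (rather than literally resampling covariate rows
by ω, which remains available behind `resample_covariates=True`) targets the
same mixture Σ ω_i F_i with strictly lower Monte-Carlo error and sidesteps
the choice of a resample size.

*Ground truth* for simulation studies uses the same Rao-Blackwellized
pipeline with uniform weights over a large resampled covariate pool
(101 × N draws by default) and no posterior uncertainty.

## Sensitivity analysis

Assumptions: (i) (M(0), M(1)) | X follow a Gaussian copula with correlation
ρ ∈ [0, 1] and the fitted per-arm margins; (ii) the conditional mean of
Y(a, m) given the mediator pair is `expit(logit r_y(m, a, x) + λ(M(a) − m))`.
The estimator mirrors the Rao-Blackwellized average:

    Ē(a, a′) = K⁻¹ Σ ω_i expit[ logit r_y(M*(a′), a, X_i) + λ(M*(a) − M*(a′)) ]

with copula-coupled mediator pairs; comonotone coupling is *not* used for
ρ < 1 because ρ is part of the assumed model there, not a variance-reduction
device.  r_y is the conditional mean of the *fitted* ZOIB outcome model (it
is never refit); it is clamped to [1e−12, 1 − 1e−12] before the logit, with a
warning.  Within-arm means Ē(a, a) use r_y directly (the shift cancels), so
τ is exactly invariant to (λ, ρ) and λ = 0 reproduces the sequential-
ignorability estimator bit-for-bit when both are run from the same seed and
coupling — `average_effects` therefore accepts a coupling correlation `rho`
(default 1) so the two paths can share draws.  Exactness holds per draw, not
only in distribution, and is asserted in the test suite.

λ calibration: a pilot quasi-likelihood logit-link mean regression of Y on
(X, A, M) (statsmodels GLM, binomial family on the continuous response)
yields β̂_M; the default grid is 21 equally spaced values on
[−2|β̂_M|, +2|β̂_M|] (always containing 0, half-width floored at 0.05 so a
null pilot still yields a usable sweep).  The tighter range [−|β̂_M|, |β̂_M|]
is defensible as well; the wider band is the default because it is the more
conservative probe.  Default ρ grid: {0, 0.5, 0.95}.  Within each ρ the
copula draws and bootstrap weights are shared across the entire λ grid
(common random numbers), so sensitivity curves are smooth and invariances are
exact.  Quantile-effect sensitivity is out of scope: the mean-shift
assumption identifies only means.

## Synthetic study conditions

No external data ships with the package.  `datasets.synthetic_coefficients()`
fixes a base coefficient set emulating a job-training trial with bounded 1–5
scores: the outcome ("depression") carries ≈ 12% mass at its floor and ≈ 1%
at its ceiling; the mediator ("self-efficacy") ≈ 2% at the floor and ≈ 12–16%
at the ceiling; treatment effects are small and beneficial (mediator
treatment coefficient +0.12 on the β-mean logit, outcome −0.10), and higher
self-efficacy lowers depression through all three location components.  The
covariate pool has an intercept, two correlated standardized numerics and a
binary indicator; treatment is randomized with probability 1/2.  The
generator reproduces what matters for the estimators — boundary inflation,
skewed interior densities, covariate-dependent parameters, small nonlinear
effects — but real questionnaire data additionally exhibit discreteness
between the bounds, item-level missingness and measurement error, none of
which are emulated; passing tests therefore certify the estimation machinery
under the assumed sampling model, not robustness to those features.

Simulation scenarios 1–5 rescale the treatment-coefficient vectors (ξ_Y,
ξ_M) by (1, 0), (0, 1), (10, 0), (0, 10), (1, 1).  The misspecification
scenario (`datasets.misspecification_coefficients()`) puts strong treatment
effects in the beta means only (mediator +2, outcome −0.5, constant
precision) with a strongly nonlinear mediator→outcome response, the regime
in which the product-of-coefficients linear SEM comparator collapses (its
single δ estimate cannot track δ(0) ≠ δ(1)) while the ZOIB estimator stays
near nominal.  The censored-normal generator (latent Gaussian linear models
clamped to [0, 1]) provides the alternative mechanism for robustness checks.

The LSEM comparator is fit by exact conjugate flat-prior Bayesian linear
regression (normal–inverse-χ² sampling), with δ = b_A·c_M, ζ = c_A per draw.

## Problem sizes and defaults

Analysis defaults: 4 chains × 1000 retained draws, prior sd 10, K = 2
(means) / K = 10 (quantiles).  The test and acceptance suites run scaled-down
versions chosen as reasonable desk-scale studies: parameter recovery with 50
datasets of N = 2000 (4 × 400 draws per fit); operating characteristics for
the no-mediation scenario with 25 replicates at N = 450 (4 × 125 draws,
K = 2); the misspecification contrast with 25 replicates at N = 899.
`scripts/acceptance.py` analyses one N = 899 trial (4 × 500 draws), computes
ground truth with 101 × N Monte-Carlo samples, and runs a 10-replicate
scenario-1 study.

## Numerical notes and limitations

- The beta quantile uses `scipy.special.betaincinv`, evaluated only where a
  draw lands in the continuous segment; atoms short-circuit.
- Degenerate boundary probabilities (α or γ exactly 0/1) return −inf
  log-mass rather than raising, so samplers can reject gracefully.
- Replicate seeds in simulation studies derive from a master seed via
  `SeedSequence`-style spawning (`default_rng([seed, r])`), making studies
  reproducible and order-independent.
- Effects are reported on the original outcome scale (×(hi − lo)).
- Posterior predictive checks regenerate the mediator for the mediator check
  and condition on the observed mediator for the outcome check by default
  (isolating each model's fit); a joint mode regenerates both.
- Not implemented: frequentist bootstrap inference, stratified target
  populations, nonparametric (mixture/tree) response models, other inflated
  families (zero-inflated Poisson/negative-binomial/gamma/log-normal), and
  missing-data handling (missingness is a preprocessing error by contract).
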