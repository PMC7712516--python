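# Methods

`sf6dbeta` implements a Bayesian analysis pipeline for health-state utilities
elicited with the standard gamble (SG) on the SF-6D descriptive system. This
note records the models, the numerical choices behind the sampler, what the
synthetic-data generator does and does not emulate, and the design decisions
that were genuinely open.

## The descriptive system

The SF-6D classifies health on six dimensions — physical functioning (PF, 6
levels), role limitations (RL, 4), social functioning (SF, 5), pain (PAIN, 6),
mental health (MH, 5) and vitality (VIT, 5) — giving 6·4·5·6·5·5 = 18,000
states. A state is a six-digit code (`111111` = full health, `645655` = "the
pits", the worst state). The regression design uses one indicator per
(dimension, level > 1) pair, 25 dummies in all, so full health is the
reference and every coefficient is a utility decrement. Two states are
*adjacent* when they differ in exactly one dimension by exactly one level;
each state therefore has 6–12 neighbors. The per-dimension level counts are
pinned down jointly by the pits code and the 18,000 total, and are asserted
by a test.

## Preprocessing

Each respondent values seven design states against full health, plus the pits
against full health and death. Pits valuations below −1 are bounded at −1
("worse than death" stays on the scale). The pits value P re-anchors the
other valuations onto the death = 0 / full-health = 1 scale:

    SGADJ = SG + (1 − SG) · P

and the pits task itself enters the dataset as y = bounded P. Respondents
whose eight values never change (exact equality by default; a tolerance knob
exists for floating-point fixtures) are excluded — they carry no preference
information. The filter runs on adjusted values; running it on raw values
would flag the same respondents whenever P ≠ 1, which is guaranteed here.

Values of y ≤ 0 or ≥ 1 are legal preprocessing output (the linear models can
use them), but beta-family fits require y strictly inside (0, 1) and raise an
error by default; an optional boundary compression y′ = (y(n−1) + 0.5)/n is
available because boundary values are possible in principle even though
typical SG studies of this design produce none.

Covariate coding: age stays continuous in years; gender and degree are 0/1;
housing, income and marital status are three-category variables coded as two
dummies each (HOUSING1/2, INCOME1/2, MS1/2) against reference category 0.
The reference categories are arbitrary and matter only for the intercept.

## Models

With y_i the adjusted utility of record i, x_i the design vector (intercept,
25 dummies, optionally 9 covariate terms) and respondent r(i):

* **Linear (LR):** y_i = x_i'β + ε_i, ε_i ~ N(0, σ₂²).
* **Beta (BR):** y_i ~ Beta(μ_i φ, (1 − μ_i) φ) with logit(μ_i) = x_i'β, so
  E(y_i) = μ_i and Var(y_i) = μ_i(1 − μ_i)/(1 + φ); φ is a precision.
* **+RE:** a respondent intercept b_{r(i)} ~ N(0, σ₁²) is added to the linear
  predictor — before the logit in the beta family — capturing consistently
  high or low valuers.
* **+COV:** respondent covariates appended to x_i.

Priors are deliberately vague: β ~ N(0, 10⁶) componentwise and
IG(0.001, 0.001) on σ₁², σ₂² and φ. Two weakly-informative alternatives are
switchable per model: a flat prior on σ (p(σ²) ∝ σ⁻¹) for the variance
components, and φ = U² with U ~ Uniform(0, a), default a = 50 (so φ < 2500
with density ∝ φ^{−1/2}). No truncation is imposed on φ under the default
prior.

## Sampler

Protocol: 2 chains (configurable), 5,000 burn-in iterations and 10,000
retained draws per chain by default; tests and the acceptance script use
shorter chains (stated below) because the fitted posteriors are
low-dimensional and mix quickly at this data size.

* **Linear family — pure Gibbs.** β | σ², b is multivariate normal
  (Cholesky solve of the p×p precision each sweep), b_i | rest is normal,
  and σ₂², σ₁² | rest are inverse gamma. Under the flat-σ alternative the
  conditional becomes IG((n−1)/2, SSR/2).
* **Beta family — Metropolis within Gibbs.** No conjugacy except
  σ₁² | b (inverse gamma, kept as a Gibbs step). β coordinates are updated
  one at a time by Gaussian random-walk Metropolis with per-coordinate
  proposal scales; because each dummy column touches only the records of a
  few states, the linear predictor and per-record log likelihood are updated
  incrementally on the affected rows only. Two sweeps over β per iteration
  (configurable) roughly halve the coefficient autocorrelation at modest
  cost. φ is updated on the log scale (Jacobian in the acceptance ratio).
  The random intercepts are proposed jointly with a shared scale and
  accepted per respondent — valid because the b_i are conditionally
  independent — using contiguous per-respondent segment sums.
* **Recentering move (RE models).** The intercept and the mean of the random
  effects are identified only by the priors, so both samplers add one extra
  Gibbs step per iteration along that likelihood-invariant direction: a
  shift δ with (β₀, b) → (β₀ + δ, b − δ) leaves every linear predictor
  unchanged, and its full conditional is Gaussian in the two priors. Without
  this move the intercept mixes by a slow random walk against the mean of b.
* **Adaptation.** All proposal scales are tuned by Robbins–Monro
  (γ_t = t^{−0.6}) toward a 0.35 acceptance rate during burn-in only and are
  frozen afterwards, so the retained chain is a valid fixed-kernel Markov
  chain. Post-burn-in acceptance rates are recorded per block and land in
  [0.1, 0.6] on study-sized data.
* **Initialization.** β starts at 0 with the intercept at the (logit of the)
  grand mean; φ at 10; variance components at 0.1. Later chains are
  overdispersed with N(0, 0.5²)·chain-index jitter per coefficient and
  log-normal (sd 0.5·chain-index) factors on φ and the variances. Jitter on
  the scale of the β prior sd (10³) would put the beta likelihood at exactly
  −∞ (saturated logits), so "broadly spread" is implemented on the scale of
  the posterior, not the prior; a non-finite log posterior at initialization
  is an error.
* **Convergence.** The Gelman–Rubin potential scale reduction factor
  R̂ = sqrt(((n−1)/n·W + B/n)/W) is computed per scalar (including every
  b_i). "About 1" is made concrete as R̂ < 1.1; summaries warn (non-fatally)
  above that. A parameter constant in all chains reports R̂ = 1 by
  convention.
* **Determinism.** Every chain draws from a `numpy` Generator spawned from a
  single `SeedSequence`; the same seed reproduces draws bit for bit.

Posterior summaries are pooled over chains: mean, sd, and equal-tailed 2.5%
/ 97.5% percentile intervals (the interval type is a choice; highest-density
intervals would differ slightly for the skewed variance posteriors).
Coefficients whose interval excludes zero are flagged.

## Evaluation

* **MPE** is implemented as mean absolute error and **RMSE** as the root
  mean squared error. The aggregation level (individual records vs per-state
  mean utilities) changes both numbers substantially, so it is an explicit
  parameter and the CLI reports both levels. The reference tables' RMSE
  footers reproduce from their own columns; their MPE footers do not, under
  MAE or any other simple definition we tried, so no MPE value is asserted
  against them.
* **Predicted state utility** is the posterior mean (and sd) over draws of
  the population-level utility with the random effect at 0 (the median
  respondent) and covariates at reference values: inverse-logit of x'β for
  the beta family, x'β for the linear family. Marginalizing over b instead
  would shrink beta-family predictions toward 0.5; the plug-in convention
  reproduces the reference per-state predictions (e.g. the pits at ≈ 0.331
  from the published BR+RE means).
* **DIC** uses the conditional (random-effects-focused) deviance:
  D̄ = E[−2 log L] over draws, p_D = D̄ − D(θ̂) at the posterior mean of all
  sampled quantities including b, DIC = D̄ + p_D; lower is better. For the
  fixed-effects linear model p_D ≈ 27 (26 coefficients + 1 variance), the
  standard near-normal identity.
* **Monotonicity audit.** Over adjacent pairs sampled uniformly (first state
  without replacement, partner uniform among its neighbors), a pair is a
  violation when the worse state (higher level in the differing dimension)
  has the *strictly* higher predicted utility. Ties are not violations by
  default because 3-decimal rounding of published coefficients creates
  spurious ties; a strict mode counts them.
* **Leave-one-state-out.** For each held-out state the model is refitted on
  the remaining states' records, the omitted state is predicted, and the
  standardized residual (obs − pred)/sd is reported, plus Q–Q points of the
  standardized residuals against normal quantiles at (i − 0.5)/n plotting
  positions. Plotting itself is left to the caller; the point sets are the
  deliverable.

## Synthetic studies

The generator emulates the study design the models target: 126 respondents
assigned round-robin to 7 blocks of 7 states from a 49-state panel, plus the
pits anchor task for everyone — 1,008 valuations, every non-pits state valued
18 times, the pits 126 times. Utilities follow the BR+RE data-generating
process: b_i ~ N(0, σ_b²), μ = expit(x'β_true + b_i), y ~ Beta(μφ, (1−μ)φ),
with draws within 10⁻⁶ of a boundary redrawn (truncation would distort the
likelihood; redraws keep it exactly beta at negligible rejection rates).

Defaults are fixed once: β_true is the published BR+RE posterior-mean vector
(so state means span ≈ 0.33–0.89), φ = 9.943, and σ_b = 0.3 on the logit
scale — with the intercept at 2.175 this puts respondent full-health
utilities in ≈ (0.83, 0.94), a plausible between-respondent spread for SG
data. Covariates are generated (age uniform over 18–65, categorical variables
uniform) but carry zero effect, matching the observation that no covariate
interval excluded zero. Optionally, a chosen number of respondents have all
eight values overwritten with a single constant to exercise the exclusion
filter; with 2 such respondents the filter retains exactly 992 records
(98.4%).

A raw-SG layer is synthesized by algebraic inversion of the anchoring
formula (SG = (y − P)/(1 − P)), not by simulating the ping-pong elicitation,
so preprocessing round-trips the generated utilities to machine precision.

What the generator does *not* emulate — and hence what passing tests do not
establish about real data: probability-grid rounding and framing effects in
elicitation, worse-than-death responses (all generated utilities are
positive), uneven recruitment (real studies show 17-vs-18 replication
imbalance; blocks here are balanced), respondent-level heteroscedasticity
beyond the shared φ, and any genuine covariate effects.

## Problem sizes used in tests and the acceptance script

Parameter recovery runs 20 replicates of the full 126×8 design with 2 chains
of 1,000 burn-in + 2,000 retained draws; at this size pooled 95%-interval
coverage of the 25 dummy coefficients sits within binomial bounds and all
R̂ < 1.1. The acceptance script fits LR+RE and BR+RE with the same chain
lengths, audits 10,000 adjacent pairs, holds out 10 states for LOO (500 +
1,000 draws per refit) and runs a 5-replicate recovery pass at the full
chain length. These sizes are
the package's test-scale defaults; the full protocol (5,000 + 10,000) is the
library default for real analyses.

## Known limitations

* The published coefficient tables are the only bridge to the original
  study; its raw 992 valuations are not deposited, so model coefficients,
  DIC values and the published 15%/10% non-monotonicity fractions are not
  reproducible from scratch — they depend on the unavailable data and on
  unstated tie-handling. The package checks itself by parameter recovery on
  synthetic data and by recomputing the published worked examples from the
  shipped tables instead.
* Coordinate-wise Metropolis is robust but not the fastest mixer for highly
  correlated coefficient blocks; at this design (orthogonal-array states,
  n ≈ 1,000) autocorrelation is mild and 2,000 retained draws suffice.
* The heteroscedastic linear extension (non-constant error variance) and
  dispersion-covariate beta regression are out of scope, as are informative
  cross-study priors.
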