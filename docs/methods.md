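# Methods

This note documents the statistical models, priors, sampler, and the
numerical and design choices behind `paircomp`, in the spirit of the
methods documentation of packages like statsmodels or msprime.

## Models

A contest is a pairwise comparison between players *i* (listed first,
"player0") and *j* with outcome win-i / win-j / tie.  All models assign
each player a latent log ability and turn ability differences into
outcome probabilities.

**Bradley–Terry (`bt`).**
P[i beats j] = exp(θ_i) / (exp(θ_i) + exp(θ_j)); the observed winner is a
Bernoulli draw.  Equivalently logit P = θ_i − θ_j, so probabilities
depend on differences only and the absolute level of θ is unidentified;
the zero-mean prior supplies the missing location (a *soft constraint*
rather than a hard sum-to-zero restriction).

**Davidson (`davidson`).**
Adds a tie outcome with weight exp(ν + (θ_i + θ_j)/2) — the geometric
mean of the two ability weights scaled by exp(ν) — and normalizes the
three outcomes jointly.  We implement the likelihood as a single
three-outcome categorical per contest.  Some presentations write the
win and tie components as two separate Bernoulli statements; the joint
normalization of that pair is ambiguous, whereas the categorical form
preserves the intended outcome probabilities, guarantees they sum to
one, and yields well-defined per-contest terms for WAIC/LOO.  Note the
"win given not tie" label sometimes attached to the win expression is a
misnomer: with the tie weight in the denominator it is the
*unconditional* win probability, and that is what we compute.
Limits: ν → −∞ removes ties (recovering `bt`); at ν = 0 an even matchup
gives each outcome probability 1/3.

**Order effect (`ordereffect`).**
A shift γ added to the second-listed player's log ability, multiplied by
a per-contest indicator z ∈ {0, 1}: θ_j + γz.  γ < 0 favours the
first-listed player.  If the data carry no order column, z = 1 for every
contest (the effect is presentation order itself, which every contest
has).  Under Davidson the shifted θ_j + γz is used everywhere θ_j
appears, *including inside the tie term's average*, which keeps the three
probabilities normalized; the combined Davidson-plus-order form is not
fully pinned down in the literature we follow, and this is the choice
that preserves normalization.

**Generalized (`generalized`).**
Free abilities are *replaced* by a linear predictor λ_i = Σ_k X_ik β_k
over player covariates.  No free intercepts are kept alongside the
linear form — an intercept is not identifiable here.  Covariates should
be standardized (mean 0, sd 1) because all β share one prior scale;
fitting with unstandardized columns emits a warning but is not blocked,
and covariates are never silently transformed.

**Subject random effects (`U`).**
θ_{i,s} = λ_i + U_{i,s} with U_{i,s} ~ N(0, U_std²) and a half-normal
hyperprior on U_std.  This models the dependence induced by one subject
judging many pairs (multiple judgment sampling): N·S random effects plus
one scale.

**Subject-specific predictors (`subjectpredictors`).**
θ_{i,s} = λ_i + Σ_k x_{s,k} S_{i,k}: one coefficient per (player,
covariate), K·N in total.  The covariate value is a property of the
subject; its *effect* is player-specific.  We store subject covariates
as one value per (subject, covariate) and broadcast it across players'
coefficients.

All extensions add linearly on the log scale and can be combined freely
with either base, e.g. `davidson-ordereffect-U`.

## Priors and their defaults

| parameter | prior | default scale | rationale |
|---|---|---|---|
| λ_i (abilities) | N(0, σ²) | sd = √3 (var 3.0) | weakly informative; allows win probabilities up to ≈ 0.99997 at a ±3 sd gap while still regularizing and identifying the location |
| β_k (player covariates) | N(0, σ²) | sd = √3 | same scale as abilities, assuming standardized covariates |
| S_{i,k} (subject predictors) | N(0, σ²) | sd = √3 | as above |
| U_std (random-effect scale) | Half-N(σ) | σ = √3 | allows large between-subject variance while weakly informative |
| ν (tie balance) | N(0, σ²) | sd = 1.0 | centered at "ties driven by abilities alone" |
| γ (order effect) | N(0, σ²) | sd = 1.0 | centered at "no order effect", symmetric in direction |

All scales are user-configurable (`PriorConfig`).  Larger ability-prior
scales weaken the soft identification and can produce divergent chains;
much smaller ones shrink all abilities together.

## Sampler

The posterior is sampled with an in-package No-U-Turn Hamiltonian Monte
Carlo sampler (slice-sampling doubling variant) over the unconstrained
parameter vector, using analytic gradients of the composed log density.

- **Parameterization.**  Random effects are non-centered:
  U = U_std · U_raw with U_raw ~ N(0, 1) and U_std sampled on the log
  scale (log-Jacobian included).  This is mathematically identical to
  the centered hierarchical prior but has much better sampler geometry
  when the data only weakly determine U_std.
- **Likelihood evaluation.**  Contests sharing (players, subject, order,
  outcome) collapse to one weighted categorical term, so the cost per
  gradient depends on the number of distinct matchups, not raw contests.
- **Initialization.**  Each chain starts uniform in [−2, 2] on the
  unconstrained scale (standard HMC practice); a non-finite density
  after 100 tries raises an initialization error suggesting smaller
  prior scales.
- **Warmup.**  Dual averaging adapts the step size toward a target
  acceptance statistic (default 0.9).  The first three quarters of
  warmup run on the unit metric; draws from the middle window estimate
  the metric (shrunk toward unity, Stan-style n/(n+5) regularization),
  after which the step size is re-tuned and refined for the remaining
  quarter.
- **Metric.**  Diagonal or dense, default "auto": dense for dimension
  ≤ 32, diagonal above.  The ability posterior is a narrow ridge along
  the common-shift direction (tight contrasts, prior-scale location), a
  correlation structure a diagonal metric cannot remove; the dense
  metric decorrelates it and roughly triples effective sample sizes per
  iteration in the recovery study below.  For high-dimensional
  random-effect models the covariance estimate from warmup draws becomes
  noisy and the diagonal default is safer.
- **Divergences.**  A transition is flagged divergent when the energy
  error exceeds 1000 (the conventional threshold).  Tree depth is capped
  at 10 by default.
- **Determinism.**  One `numpy` SeedSequence per fit, spawned per chain;
  identical (data, config, seed) reproduce draws bit-for-bit for a fixed
  backend version.  Cross-version bit-equality is not promised.

## Convergence diagnostics

`check_convergence_diagnostics` fails a fit when any of these documented
rules fire, and lists each violated rule:

- split R̂ ≥ 1.01 for any parameter (rank-normalized split formulation;
  the plain Gelman–Rubin variant is available behind a flag);
- effective sample size < 200 for any parameter (the rule-of-thumb
  minimum for estimating a posterior mean; more is needed for extreme
  quantiles) — bulk ESS via `arviz`;
- any divergent post-warmup iteration;
- E-BFMI < 0.2 for any chain (energy exploration too slow).

Maximum-treedepth hits are reported as an *efficiency warning*, not a
validity failure.  Thresholds are inclusive exactly as written (a
parameter at R̂ = 1.01 fails; ESS = 200 passes; E-BFMI = 0.2 passes).

## Posterior products

- **HPD intervals** are computed exactly on the draws: among all windows
  of ⌈mass·n⌉ consecutive order statistics the narrowest is returned
  (ties broken toward the lowest lower bound).  For symmetric unimodal
  posteriors HPD and equal-tailed intervals coincide; for skewed ones
  the HPD interval is shorter.  The default report uses 95% HPD.
- **Ranks.**  Within each retained draw players are ranked by descending
  effective ability (rank 1 = best); ties within a draw are broken by
  player index, a probability-zero event for continuous posteriors.  The
  table reports median/mean/sd of each player's rank; mean ranks always
  sum to N(N+1)/2.
- **Probability tables** report the posterior mean of the model
  probability per ordered pair (optionally with HPD intervals over the
  per-draw probabilities).  The mean of the per-draw probability is not
  the probability at the posterior mean — the nonlinearity matters for
  dispersed posteriors, and the per-draw average is the predictive
  quantity.  For subject-varying models the default "average subject"
  sets random effects and subject-covariate contributions to zero rather
  than integrating over subjects; per-subject tables are available on
  request.  Odds ratios are P/(1−P) for `bt` and P(i wins)/P(j wins)
  for `davidson`.
- **Predictions** resample a posterior draw per simulated outcome, then
  draw the outcome from that draw's win/tie probabilities; seeded.
- For generalized models, reports use covariates exactly as fitted (the
  standardization transform is recorded on the covariate table so
  coefficients can be back-transformed).

## Model comparison

WAIC and PSIS-LOO are computed from the (draw × contest) pointwise
log-likelihood matrix; the pointwise unit is one contest (one categorical
outcome), including under random effects (leave-one-subject-out is out of
scope).  WAIC uses the variance-based penalty p_waic = per-observation
posterior variance of the log-likelihood; log-mean-exp is max-shift
stabilized.  LOO uses Pareto-smoothed importance sampling
(`arviz.stats.psislw`) and reports per-observation Pareto k, warning
above 0.7.  The headline number is the deviance scale −2·elpd (smaller
is better).  AIC and BIC are deliberately absent: they assume flat
priors and MAP estimation, which do not hold here.

## The simulator

`simulate_contests` draws outcomes from the exact model probabilities
given true parameters — it is the generative dual of every likelihood in
the package, and is what the recovery and model-selection studies use.
Default pairing is a full round-robin repeated to the requested size
(unbalanced designs confound recovery tests); uniform random pairing is
available.  Subjects are assigned cyclically; order indicators are all-1
by default (alternating and random schemes available).  True ability
vectors should be centered so that recovery is assessed on identified
contrasts.

What the simulator does *not* emulate about real preference data:
judge-level drift over time, context or carry-over effects between
successive comparisons, misreported outcomes, and non-ignorable missing
pairs.  Passing recovery tests therefore demonstrates correctness of the
inference machinery under the model, not robustness to violations of it.

## Validation studies and problem sizes

The test suite's end-to-end studies use sizes chosen to give stable
verdicts at desk scale:

- parameter recovery: 5 players, true λ = (1, 0.5, 0, −0.5, −1), 2000
  contests, 20 replicate datasets, 4 chains × 1000 retained draws each;
  95% HPDs of adjacent ability contrasts must cover truth in ≥ 80% of
  replicates and diagnostics must be clean in ≥ 18/20;
- model selection: 20 replicates of 1000 contests generated with no
  order effect, fitting `bt` and `bt-ordereffect`; the superfluous
  parameter must not improve WAIC in a clear majority (WAIC is noisy, so
  "all 20" would be the wrong bar);
- oracles: the HPD routine against an exhaustive window search, WAIC
  against an independent transcription of its formula, two-player
  posteriors against 1-D grid integration (exact for contrasts, since
  the prior factorizes over sum and difference directions).

## Known limitations

- Pure-Python sampler: fits with many thousands of distinct matchups or
  very large random-effect blocks are slower than compiled samplers;
  the matchup aggregation removes most of the cost for typical designs.
- Only pairwise data (no partial rankings of three or more items), no
  sequential/time-varying abilities, no probit (Thurstonian) link, no
  conjugate-prior estimators, no variational or MAP-only modes.
- The score-to-result rule (`results_from_scores`: higher score wins,
  equality is a tie only when allowed) and the `ties=drop` option are
  package conventions for conveniences whose exact behaviour is not
  standardized in the literature; both are explicit and logged rather
  than silent.
- Dense-metric adaptation assumes the warmup window reflects the
  stationary posterior; badly initialized chains with very short warmup
  can mis-estimate it (the shrinkage toward unity bounds the damage).
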