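# Methods

## Problem

A finite population of `n` individuals is to be recruited into a study of
target size `m`, by walking through the population list once and deciding,
one individual at a time, whether to send an invitation.  Each individual
`i` carries auxiliary variables `x_i` known a priori (from a registry) and
an initial inclusion probability `pi_i^(0)` with `sum_i pi_i^(0) = m`.  Two
complications drive the design:

* **Unknown participation.** An invited individual accepts with probability
  `phi_i = p(s_i = 1 | b_i = 1)`, which is not known before recruitment.
* **Delayed response.** An individual invited at evaluation `i` answers
  only after evaluation `i + t_i`, with `t_i` a random delay.

## Sequential updating

The recruiter evaluates individuals in list order.  After individual `i`'s
outcome `s_i` is determined, the inclusion probability of every
not-yet-evaluated individual `j` moves by

    pi_j  <-  pi_j - (s_i - pi_i) * w,

where the weight `w` is the preliminary weight `w~_i(j)` clamped into

    w <= min( pi_j / (1 - pi_i),  (1 - pi_j) / pi_i ),

which guarantees all probabilities stay in `[0, 1]`.  When each target's
preliminary weights sum to one over its sources, the realized sample size
concentrates near `m`; weights concentrated on close neighbours in
auxiliary space make close pairs negatively correlated in the sample, which
is what produces a *well-spread* sample.

The implementation uses the equivalent **column-wise** form: at evaluation
`i` it recomputes `pi_i^(i-1)` by sweeping over all previously evaluated
`k < i`, using the stored values `pi_k^(k-1)`.  The two forms agree exactly
(clamping included) when all responses are observed; the test suite checks
this to 1e-12 against an independent row-wise reference implementation.
The column form matters because of delays: any `s_k` not yet observed is
replaced by its estimated expectation `phi_hat_k * b_k`, and because the
sweep is recomputed from scratch each evaluation, a response that arrives
later is automatically incorporated with its true value in all subsequent
evaluations.  The sweep is O(n^2) per run and is implemented as a numba
kernel.

### Weight schemes

* `zero` — probabilities never move ("simple random sampling"): invitations
  are independent.
* `uniform` — `1/(n-1)` on everyone else: pure sample-size control.
* `knn` — `1/k` on the `k` nearest neighbours (Mahalanobis distance by
  default, computed by whitening `x` with the population covariance and
  querying a Euclidean k-NN index): local balance, hence spread.
* `group` — `1/(n_g - 1)` within the individual's group: balance within
  disjoint strata.  Singleton groups fall back to `zero` behaviour (the
  within-group weight is undefined).
* `linear_rank` — `mu + c * lambda` in the distance rank `c` with
  `lambda <= 0`, clipped at zero and renormalized to sum to one.  Negative
  weights (which would create positive pair correlation) are out of scope.

Distance-rank ties are broken by the smaller individual index (stable
sort), making ranks deterministic.

## Adaptive participation correction

Individual `i` is invited with probability
`min(1, pi_i^(i-1) / phi_hat_i)`, so that the unconditional inclusion
probability approaches the design value despite non-participation.  When
`pi / phi_hat > 1` the desired inclusion probability is unreachable (an
individual can be invited only once); the cap is applied and the event is
counted in the run trace.

`phi_hat` comes from a Bayesian logistic model fitted to all invitees whose
response has been observed:

* linear predictors: intercept only; intercept + linear covariates `z`; or
  one coefficient per group with no shared intercept;
* independent normal priors on all coefficients, mean 0 and variance 100 by
  default — effectively flat, giving `phi_hat = 0.5` before any responses
  arrive;
* posterior approximated by a Laplace fit (Newton with backtracking and a
  Newton-decrement stop; warm-started from the previous refit).  For the
  one-hot designs (intercept-only, group) the posterior factorizes and is
  fitted coordinate-wise from per-cell success/trial counts — algebraically
  the same Laplace fit, at O(p) cost;
* `phi_hat_k` is the posterior-predictive mean of `invlogit(eta_k)`,
  computed by 40-node Gauss–Hermite quadrature over the (normal) linear
  predictor.  A plug-in variant (`invlogit` at the posterior mode) is also
  exposed; the predictive mean is the default since the update step is
  defined as an integral over the posterior.  An MCMC backend (emcee) is
  available as a cross-check and is off by default — the refit runs
  thousands of times per recruitment.

The posterior is refit at every evaluation at which at least one new
response arrived.  `phi_hat` is a deterministic function of the current
posterior; the implementation evaluates it lazily (with a per-individual
version cache) for exactly the individuals a step touches — the current
individual and the pending invitees — which is mathematically identical to
refreshing the full vector after each refit.  For invitations still
pending inside the sweep we use the *latest* posterior, not the one frozen
at invitation time; the update rule indexes the estimate by the current
evaluation, and the latest posterior is the better estimate of the same
quantity.

## Spread diagnostic

For a recruited set `s`, every population individual is assigned to the
nearest participant in auxiliary space (a Voronoi polytope); exact `t`-way
distance ties contribute `1/t` to each tied polytope.  With
`q_i = sum_{j in v_i} pi_j^(0)`, a well-spread sample has every `q_i` close
to 1, and the scalar measure is

    R = (1 / |s|) * sum_{i in s} (q_i - 1)^2 .

Two normalizations exist in the literature; this package exposes both and
defaults to dividing by the number of participants `|s|`, the convention
under which the two benchmark samplers land at median R of roughly 0.24
(independent invitations) and 0.19 (50-NN weights) in the continuous
benchmark — dividing by the population size `n` instead yields values ten
times smaller under the same designs.  Distances are rounded to 12
significant digits before the nearest-participant comparison so that tie
splitting is reproducible across BLAS variants.

## Estimation

The population total is estimated by Horvitz–Thompson with the *initial*
inclusion probabilities, `Y_hat = sum_{j in s} y_j / pi_j^(0)`.  Joint
inclusion probabilities, needed for the variance estimator, have no closed
form under this design and are approximated by the Hájek formula

    pi_ij ~= pi_i pi_j [ 1 - (1 - pi_i)(1 - pi_j) / d ],
    d = sum_k pi_k (1 - pi_k),

validated against Monte-Carlo pairwise selection frequencies (within 1% on
the uniform n=1000 design).  Confidence intervals are Wald intervals;
negative variance estimates (possible for pathological designs) are
flagged rather than truncated so that coverage bookkeeping stays honest.

## Synthetic benchmark populations

Two generators define the study conditions and are used by the experiment
drivers and the acceptance script.

**Continuous benchmark** (`n = 4000`, `m = 400`, `pi0 = 0.1`): covariates
`z ~ MVN(0, I_4)`; auxiliary `x ~ MVN(0, Sigma)` with the fixed 4x4
`Sigma` (unit variances; off-diagonals 0.20, -0.50, 0.30, 0.20, -0.40,
-0.20); participation `invlogit(1 + z' (0.3, -0.7, 0.1, 0.4))` (mean about
0.70); delays `Poisson(15)`.  Compared samplers: zero weights, uniform
weights, 50-NN Mahalanobis weights; each under the full and the
(misspecified) intercept-only participation model.

**Five-group benchmark** (`n = 5000`): group frequencies (40, 20, 20, 10,
10)%, group participation (50, ..., 90)%, outcome prevalence (10, ...,
50)%, `pi0` = (0.05, 0.10, 0.10, 0.20, 0.20) by group — oversampling the
small groups toward equal group counts among participants; delays
`Poisson(15)`.  The analytic expected total is `E(Y) = 1150`.  Compared
samplers: zero weights vs within-group weights, both with the group
participation model.

What these generators do *not* emulate about real recruitment: covariates
are clean and fully observed (no missingness or linkage error), the
participation model is exactly the fitted family (no structural
misspecification beyond the intercept-only variant), delays are
independent of willingness to participate, and no one responds twice or
outside the modelled channel.  Passing benchmarks therefore demonstrates
the mechanics of the adaptive design, not robustness to those features.

## Experiment conventions

* Replicate `r` derives all randomness from `base_seed + r`, spawning
  separate streams for the population, the response oracle and the
  invitation decisions, so all sampler variants within a replicate face the
  same population and response randomness (paired comparisons).
* Populations are regenerated each replicate; estimator bias is measured
  against each replicate's realized total (the stricter convention; a
  fixed-population mode exists as a config switch).
* The evaluation order is the generated row order; no shuffling is applied
  by default (the CLI exposes an opt-in shuffle for sensitivity checks).
* Reported scales: the spread study runs 100 replicates and the estimation
  study 200 in the test suite and acceptance script (the studies' native
  scale is 1000); medians and intervals of R, means/SDs of participant
  counts, and bias/variance/MSE/coverage of the HT estimator are aggregated
  exactly as reported by the experiment drivers.

## Numerical choices

* Laplace Newton: per-observation gradient tolerance 1e-6, Newton-decrement
  stop at 1e-13 relative to the objective, backtracking halving, hard
  failure if the final gradient is large.  Tolerances are far below the
  precision that invitation decisions can resolve.
* Bound clamping treats a ratio with zero denominator and positive
  numerator as +inf (the limit of the admissible interval); an update whose
  `s_k - pi_k^(k-1)` factor is zero contributes nothing regardless of the
  bound.  Probabilities are clipped against round-off at the interval ends.
* Gauss–Hermite: 40 nodes; the predictive mean of a logistic transform of
  a normal with SD up to ~10 (the prior) is accurate to well below 1e-3
  (checked against 1e6-draw Monte Carlo).
* When the invitation cap fires, subsequent updates keep using the desired
  `pi_i^(i-1)` — not the realized, capped probability — exactly as the
  update rule is written; the shortfall count is a run diagnostic.

## Known limitations

* Each individual is evaluated exactly once; re-evaluating non-invitees to
  hit the target size exactly, and multiple invitation channels, are out of
  scope.
* The Hájek approximation targets high-entropy fixed-size designs; the
  zero-weight variant has independent invitations, for which the estimator
  underestimates the variance (visible as sub-nominal interval coverage in
  the five-group benchmark — the same pattern the adjusted design is there
  to fix).
* Sample-size control degrades when many invitation probabilities are
  capped at 1 (participation far lower than the design anticipates).
* The k-NN weight builder assumes continuous auxiliary variables without
  exact duplicates; ties at machine precision are resolved by index order.
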