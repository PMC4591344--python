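# Methods

## Model

One field under management action *a* (a crop plus its associated
practices) carries `Y_t` viable seeds per m² entering year *t*. The annual
update is: germination first, `X_{t+1} ~ Binomial(Y_t, σ_a)`; mortality
among the seeds that stayed behind, `D ~ Binomial(Y_t − X_{t+1}, 1 − s_a)`;
then the emerged plants' seed rain is added, `R ~ Poisson(φ_a X_{t+1})`
(a `deterministic` production mode, `R = round(φ_a X_{t+1})`, exists for
oracle tests). Plants never carry over between years (therophytes), seeds
in the bank are exchangeable (no ageing or depth structure), and there is
no density dependence. These are modelling assumptions, not conveniences:
everything downstream inherits them.

Surveys record only the emerged layer, censored to the four-class
semi-quantitative scale {0}, {1–2}, {3–20}, {>20} plants/m². The hidden
seed bank uses a finer six-class grid (adding {21–60}, {61–100}, {>100}).
Both grids are configurable; the defaults are the scales above. When a
count must be drawn *from* a class, the open-ended top class is truncated
at a cap (default 300 for the seed bank, 100 for emerged) — large enough
that class membership of the dynamics is essentially unaffected; the test
suite checks sensitivity to caps 200/300/500.

## Transition kernels

The class-level HMM needs two conditional tables per action: emergence
`P_a(c_x' | c_y)` and bank update `P_a(c_y' | c_x', c_y)`. Both integrate
the count dynamics over class intervals with the seed count uniform within
its class — the state-aggregation assumption at the heart of the method.

Two estimators are implemented:

* **Monte Carlo** (`estimate_kernel_mc`): K simulated one-year trajectories
  per bank class (default K = 30,000), tabulated into relative
  frequencies. Inside optimisation, kernels are generated with common
  random numbers (stream seeded by a per-fit base seed and the action
  index), making the MC likelihood a deterministic function of the
  parameters.
* **Exact enumeration** (`exact_kernel_enumeration`): sums binomial and
  Poisson probabilities over every count combination. The survivor pmf
  only needs arguments up to the largest finite class boundary (100), so
  the bank-update probability for a (Y, X′) pair is a ≤101-term dot
  product between a Binomial(Y−X′, s) row and a Poisson CDF table; plant
  counts whose seed rain overshoots the top boundary with probability
  ≥ 1 − 1e−16 are assigned to the top class directly. Poisson CDFs are
  built by the pmf recurrence (exp underflow at huge means correctly
  yields 0). Germination outcomes with pmf ≤ 1e−15 are dropped;
  rows are renormalised, so row-stochasticity holds to machine precision.
  The enumeration is deterministic and is both the default inference
  backend and the oracle the MC estimator is tested against.

(c_y, c_x′) pairs with zero emergence support get a uniform bank-update
slice and a `support_mask` of False; the likelihood can only reach them
with factor 0, so the filler never influences results. Survivor and
seed-rain sub-tables are memoised on `s` and `φ` respectively, which makes
component-wise MCMC (one trait moved at a time) substantially cheaper.

## Likelihood and estimation

The probability of one field's series marginalises the hidden bank classes;
`forward_loglik` implements the scaled forward recursion,
`brute_force_loglik` the literal nested sum over all 6^T hidden sequences
(guarded to T ≤ 7; oracle only). Fields are independent, so the species
log-likelihood is a sum over series; it is evaluated batched across all
series. Zero-probability sequences are floored at −1e10 rather than −∞ so
optimisers can still rank candidates.

**Maximum likelihood** uses a Price-type controlled random search in the
bounded box σ, s ∈ [0,1], φ ∈ [0, φ_max] (default φ_max = 200,
configurable upward for prolific taxa) and five additive-log-ratio
coordinates for the initial bank-class law p0 (reference class 6, ALR box
±8 — ratios up to e⁸ ≈ 3000, far wider than any plausible p0). One p0 is
shared per species: a per-field p0 would add five parameters per field and
be unidentifiable. The reflection simplex always contains the current best
member, which in this 17-dimensional box converges far faster than
uniformly random simplices at equal evaluation budget; because the
exact-backend likelihood is smooth and deterministic, a bounded
derivative-free Powell polish then runs from the incumbent (on by default,
`polish=False` restores the pure random search). Defaults: population
10·(dim+1), at most 50,000 iterations, stop when the population's
log-likelihood spread < 1e−6.

**Bayesian estimation** is component-wise random-walk Metropolis within a
Gibbs sweep under uniform priors over the same box, on transformed
coordinates (logit for σ and s, log for φ, ALR for p0) with the transform
Jacobians in the target. Defaults: proposal scale 0.15 on the transformed
scale, 20,000 sweeps, 5,000 burn-in; per-coordinate acceptance rates are
recorded so scales can be tuned to the 20–50% range. Initialisation must
be strictly inside the box (the CLI clips ML output inward by 1e−4).

## Demography

`λ_a` is the dominant eigenvalue of the 2×2 annual projection. The
published matrix form, `[[s(1−σ)+σφ, 0], [σ, 0]]`, routes all dynamics
through the seed row; its growth rate has closed form s(1−σ)+σφ and its
subdominant eigenvalue is structurally zero, so its damping ratio is
*always* infinite. Because finite damping ratios are nevertheless a
meaningful demographic summary, a `two_stage` form
`[[s(1−σ), φ], [σ, 0]]` is provided as well: it books the seed rain
through the plant stage one year later, has the same growth
classification, and a non-trivial subdominant eigenvalue. Both forms are
kept and selected explicitly; `as_printed` is the default, and the
infinite damping of that form is reported as an explicit `inf`, never as a
number.

## Prediction and cross-validation

One-step-ahead prediction filters the bank distribution through the full
observed prefix, propagates one year, and reports the modal emerged class,
ties broken toward the smaller class. Conditioning on the full prefix is
the natural reading of mode-of-the-predictive prediction — a single
observation cannot determine the bank state; a `strict_single_step` mode
(filter re-initialised from p0, conditioned on the latest observation
only) is available for comparison. A prefix with probability zero raises a
warning and falls back to unconditional propagation of p0.

Cross-validation partitions fields into near-equal folds by seeded
shuffle, remainder to the first folds (329 fields over 4 folds:
83/82/82/82), refits on the complement and predicts every held-out
observation. Metrics follow the survey reading: absence efficiency
(fraction of observed class-1 records predicted class 1), presence
efficiency (fraction of observed class->1 records predicted above 1), and
signed class errors (predicted − observed) averaged over incorrect
predictions only, with their standard deviation; empty strata are reported
as "n.a.", never as 0.

Species filters for multi-species record tables: keep species with ≥ 120
occurrence records (class > 1), then drop any species for which some
(species, action) pair occurs in fewer than 10% of recorded fields.

## Synthetic surveys

The generator emulates a national monitoring campaign: 329 fields; series
lengths on {2..8} years from the maximum-entropy pmf matching mean 3.62
and sd 1.19 (solved deterministically); crop draws i.i.d. at shares
0.496/0.102/0.293/0.108 (printed shares sum to 99.9%; renormalised). A
Markov rotation option exists because real rotations are autocorrelated,
but it is beyond the surveyed design and off by default. Each field draws
its initial bank class from p0 and a count uniformly within it, then
iterates the count dynamics; emerged counts are censored to classes. The
hidden count trajectories are returned alongside the observable data for
recovery tests and never leak into the observable output.

The default simulation truth uses two contrasted life-history strategies
spread across the four actions — colonizers (higher σ, lower s) under the
annual crops, a persister (σ = 0.10, s = 0.75) under maize — with growth
rates straddling 1, so that simulated surveys contain the realistic mix of
absences, sporadic presences and persistent infestations.

What the generator does *not* emulate: spatial structure and dispersal
between fields, observation error in the class assignment, surveyor
effects, species interactions, rotation autocorrelation (by default), or
any within-season dynamics.

## What recovery experiments do and do not show

Because the generator works at the count level while the likelihood works
on class-aggregated states (counts assumed uniform within class at every
step), the fitted model is — deliberately — a misspecified approximation
of the generating process, exactly as it is for real data. Consequences,
measured in this package's experiments at the 329-field design:

* σ is precisely identified (information-based SDs 0.005–0.03), and its
  point estimates land close to the generating values; the across-action
  ranking of φ is usually preserved.
* s is weakly identified (SDs 0.12–0.44, worst for the two actions with
  ~10% frequency) and carries a systematic downward aggregation bias of
  roughly 0.05–0.15. Fitting data simulated from the class-level chain
  itself removes the bias, confirming the inference machinery is correct
  and the gap is the aggregation approximation.
* Posterior credible intervals are calibrated under the class-level model,
  not under the count-level generator: converged chains can sit several
  interval-widths away from the generating σ. Interval coverage of
  count-level "truth" is therefore poor even with perfect mixing.

Anyone applying the method to real records should read its uncertainty
statements accordingly: they quantify within-model uncertainty, not the
aggregation error.

## Problem sizes and numerical choices

Test-suite and acceptance-script experiments use: exact kernels (cap 300)
for inference; ML fits with population 80, 800 search iterations and a
2,000-evaluation polish (enough that the attained log-likelihood exceeds
the generating parameters' by the expected overfitting margin); MCMC
chains of 200 sweeps (50 burn-in, proposal scale 0.35) for interval
experiments and 4,000 fast sweeps for prior-sampling checks;
cross-validation with 500-iteration fits per fold. Monte-Carlo kernel
checks use the survey-scale K = 30,000. Ties, floors and tolerances:
predictions tie-break to the smaller class; log-likelihood floor −1e10;
kernel rows stochastic to 1e−9 (validated); kernel memoisation keys round
traits to 12 decimals.

## Known limitations

* The state-aggregation bias above is the dominant error source for s and
  φ; longer series or finer abundance scales, not more fields, would
  reduce it.
* The exact enumeration scales with the square of the top-class cap;
  caps ≫ 10³ would need a different integration scheme.
* The CLI's `.log` sidecars include wall time and are not byte-stable;
  the CSV artifacts are.
* Uniform priors on a bounded box are informative near λ ≈ 1 for large
  φ_max; posterior summaries for φ should be read with the box in mind.
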