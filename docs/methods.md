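# Methods

## Model and assumptions

The decision process is a single-stage Wiener diffusion with absorbing
boundaries at 0 and *a*, start point *z·a*, drift *v*, and unit diffusion
coefficient.  The lower boundary is the ingroup-compliant response (the
option with the larger ingroup/outgroup donor ratio).  Observed RT is the
first-passage time plus a non-decision time *t₀*.  Across-trial drift
variability *sv* is supported (each trial's drift ~ N(*v*, *sv*²));
across-trial variability of start point and non-decision time is not —
no model variant in the fitted space frees them, so they are fixed at
zero throughout rather than carried as dead parameters.

The diffusion coefficient is fixed at 1.  This is the convention of the
R estimation ecosystem for this model class (`rtdists`, `fddm`), and the
magnitudes of the fitted parameters this package is anchored to
(*a* ≈ 2, |*v*| ≈ 1–3) only make sense on that scale.  All parameters
are interpreted on the unit-diffusion scale.

## Density evaluation

The defective first-passage density at the lower boundary factorises into
an exponential drift term and the density of the driftless unit process,
which has two classical series representations.  We evaluate whichever of
the small-time and large-time expansions needs fewer terms for a
truncation error of 1e-7 at the given scaled time, choosing per
evaluation point.  Upper-boundary densities use the reflection
(*v*, *z*) → (−*v*, 1−*z*).  With *sv* > 0 the exponential drift factor
is replaced by its exact Gaussian marginal, so no extra quadrature enters
the likelihood.  Choice probabilities use the closed-form absorption
probability, marginalized by 61-point Gauss–Hermite quadrature when
*sv* > 0.

The density implementation is validated against two independent oracles:
numerical quadrature of the density must reproduce the closed-form
absorption probability to 1e-6 across a parameter grid, and simulated RT
distributions must pass a Kolmogorov–Smirnov test against the analytic
conditional CDF.

## Simulator

Trials are simulated by Euler discretization, default step 1e-4 s
(configurable).  Trials not absorbed within the 5 s response window are
censored with RT equal to the window.  The discretization overshoots
boundaries by O(√dt), which slightly biases absorption probabilities and
first-passage times; at the default step the bias is below the Monte
Carlo resolution of every check in the test suite.  All randomness flows
through explicit integer seeds; there is no global RNG state.

## Design and coding

The stimulus design is fixed: for each of three types, the 7×7 grid of
ingroup counts (type 1: [92,98]×[12,18]; type 2: [92,98]×[52,58]; type 3:
[52,58]×[12,18]), outgroup counts filling columns to 100, each canonical
table also presented with columns swapped — 294 presentation stimuli.
Mirroring is treated as a pure column swap; the compliance and equality
labels swap with the columns, and all trial information is computed
relative to the compliant option, so screen side never enters the
likelihood.  Whether participants' trial order was shuffled within blocks
or only blocks permuted is not knowable from the design description;
sessions here shuffle all 294 stimuli and then cut six 49-trial blocks,
since the three types were interleaved for participants.  Block category
labels are cosmetic metadata.

## Covariate orientation

The information functions (A−B, A/(A−B), A/B, A/(A+B), dichotomous) are
defined on table rows with **A = the compliant option's cell** and **B =
the other option's cell**, separately for the ingroup row and the
outgroup row.  Because the response boundaries are compliant vs
non-compliant rather than left vs right option, this is the only
orientation under which a single weight β has a stable meaning across
trials (e.g. negative β₁ with percentage information = drift toward
compliance as the compliant option's ingroup share rises).  The
dichotomous information is table-wide: 1 if the largest of the four cells
lies in the queried row.  For dichotomous models with an outgroup weight
this makes outgrInfo the exact complement of ingrInfo — the two
covariates are then collinear with the intercept, which is a property of
that model variant, not of the implementation; it is enumerated as
specified and fitted like any other.

## Fitting

Likelihood: product of defective densities at the observed boundary and
RT over a subject's kept trials.  Censored trials (timeouts) are excluded
from the likelihood and counted in the preprocessing report; fewer than
~0.1 % of trials are censored at realistic parameters, so the information
loss is negligible.  Preprocessing per subject: drop censored trials,
drop RT < 200 ms, then drop trials outside Q1 − 3·IQR … Q3 + 3·IQR of the
log-RT distribution.

Optimization: L-BFGS-B on the negative log-likelihood with bounds
*a* ∈ [0.3, 5], *t₀* ∈ [0.05, min RT − 0.01] (per stimulus type when *t₀*
varies by type), *z* ∈ [0.05, 0.95], *sv* ∈ [0, 5], drifts and drift
weights ∈ [−20, 20].  Five start points by default: one heuristic
(*a* = 1.5, *t₀* = 0.9·min RT, *z* = 0.5, drifts 0, *sv* = 0.3) plus
seeded uniform draws within bounds.  Interior evaluations where a
proposed *t₀* exceeds an observed RT floor the density at 1e-300, giving
the optimizer a large finite penalty instead of an exception.  The best
converged solution is kept; if no start converges the best penalized
value is returned flagged `converged=False` and excluded from selection.

BIC uses the number of *kept* trials for each subject — n after outlier
removal, i.e. the sample the likelihood actually saw.  Cohort-level
selection averages per-subject BIC per model and takes the minimum within
each model group; ties break by fewer free parameters, then lower model
id.

## Synthetic cohort

The generator emulates the study conditions: 39 subjects (28
ingroup-driven : 11 equality-driven) × 294 trials in the fixed design,
5 s response window.  Agents share one (*a*, *z*, *t₀*, *sv*) and have a
type-specific mean drift; parameters are drawn uniformly from
strategy-specific boxes centred on the fitted subgroup estimates
(*a* ∈ [1.7, 2.3], *t₀* ∈ [0.27, 0.40] s, *z* ∈ [0.42, 0.55], *sv* = 0).
Ingroup-driven drift boxes are ±0.8 around (−2.0, −1.6, −0.9), a width
on the order of the separation between the reported subgroup estimates —
only point estimates are available, so the between-subject spread is
necessarily a modelling choice — with draws re-ordered by magnitude so
every agent satisfies |v₁| ≥ |v₂| ≥ |v₃|.  Equality-driven boxes
(v₁ ∈ [−0.8, −0.05], v₂ ∈ [0.6, 1.4], v₃ ∈ [−1.6, −0.8]) preserve the
sign pattern (type-2 drift positive) for every draw.  A covariate-drift
agent (percentage information, weights near β₀ = 1.9, β₁ = −2.8,
β₂ = −1.1) generates data for selection recovery in the covariate family.
An optional contamination process (uniform fast guesses at a configurable
rate, default off) exists solely to exercise the outlier filters.

What the generator does *not* emulate: questionnaire measures and group
identification, sequential effects, strategy switching within a session,
realistic RT contamination beyond fast guesses, or any hierarchical
(cross-subject) parameter structure.  Passing recovery tests therefore
show that the pipeline is correct and well-conditioned at realistic
parameters — not that the model family is true of human data.

## Recovery experiments and problem sizes

Parameter recovery fits the generating type-drift model to 20 simulated
subjects × 294 trials; tolerances (median absolute error ≤ 0.20 for *a*,
≤ 0.05 s for *t₀*, ≤ 0.07 for *z*, ≤ 0.50 per drift; true–estimated drift
correlation ≥ 0.8) were calibrated once on an initial oracle run and then
frozen.  Selection recovery uses five seeded replicates of reduced
cohorts (5–6 subjects) against reduced candidate sets — the family of the
generating model must win subject-mean BIC in the majority of replicates.
These cohort sizes keep a full recovery run in minutes on a single core
while leaving the per-subject trial count (the quantity that drives
estimator precision) at the full 294.

## Sensitivity power analysis

The minimum detectable effect size inverts the exact noncentral-t power
function of the two-sided one-sample/paired t test (df = n−1,
noncentrality d·√n) by bracketed root finding.  The exact distribution
matters: at n = 11, α = 0.05, power 0.80 it yields d = 0.94, where the
normal approximation lands near 0.93.  scipy's noncentral t returns NaN
deep in the tails; the implementation substitutes the known limits there.

## Quantile goodness of fit

For compliant responses per stimulus type, observed RT quantiles at
{0.1, 0.3, 0.5, 0.7, 0.9} are compared with quantiles obtained by
numerically inverting the fitted defective CDF normalized within the
compliant response (for covariate models, the CDF is the mixture over the
type's per-trial drifts).  Quantiles are computed per subject and then
aggregated across subjects.  As is typical for this model class, the 0.9
quantile is the least stable observed quantity; the central quantiles are
the meaningful diagnostic.

## Known limitations

- Point estimation only: no standard errors, no hierarchical pooling, no
  Bayesian credible intervals.
- The Euler simulator is first-order; for step sizes much above 1e-3 s
  its boundary-overshoot bias becomes visible in large samples.
- The equality-driven strategy is represented only through its drift
  signature; no explicit equality-based decision rule is modelled.
- The 294-stimulus design is fixed to the published ranges; other ranges
  are accepted by the data structures but not validated.
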