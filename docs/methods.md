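# Methods

## The data setting

`cpmct` targets *historical* expression time courses from developmental
studies in small mammals: the measured parameter (e.g. a gene's expression
level) is sampled at T ordered time points, the examination is lethal, so
every animal appears at exactly one time point — observations are
independent *across* time — while littermates at the same time point share
their mother's biology and are correlated *within* time. The design is
nested: each cluster (mother/litter) belongs to one time point. A *change
point* is a time point at which the underlying mean shifts abruptly
relative to the preceding course.

Classical change-point methods assume repeated measures on the same
subjects; dose-response trend tests assume monotone means. Neither fits.
The approach here combines three standard pieces: a linear mixed model for
the clustering, contrast matrices encoding candidate change-point
scenarios, and simultaneous confidence intervals for familywise error
control with interpretable effect estimates.

## Model

For the N-vector of analysis-scale values (expression values are
log-transformed with the **natural log** when requested; effects then read
as log mean changes),

    y = X β + Z u + ε,   u ~ N(0, σ²_c I_M),   ε ~ N(0, σ²_e I_N)

- X: N×T time-point indicators with **no intercept** (cell-means/mean
  parameterization), so β_t is the adjusted mean of time point t;
- Z: N×M cluster indicators; u are the mother effects;
- variance components (σ²_c, σ²_e) estimated by REML; β is GLS at the
  optimum with vcov(β) = (X'V⁻¹X)⁻¹, V = σ²_c ZZ' + σ²_e I.

### REML implementation

Nesting makes V block diagonal per cluster and X'V⁻¹X diagonal, so the
restricted likelihood profiles analytically down to one dimension in
θ = σ²_c/σ²_e: for a cluster of size k, (I + θJ_k)⁻¹ = I − θ/(1+θk) J_k and
log det(I + θJ_k) = log(1+θk). The optimizer is a bounded Brent search on
log θ over [−15, 15] (tolerance 1e-8, ≤200 iterations) compared against an
explicit boundary candidate θ = 0. A boundary (or within 1e-6 of it)
solution is returned flagged `singular` — standard errors may then be
underestimated; per-time-point means remain valid, so the fit is reported
with a warning rather than refused. This mirrors what a general mixed-model
fitter does for this one-random-intercept model (agreement with `lme4` is
asserted in the test suite) without general-purpose machinery.

Degrees of freedom are not estimated (no Satterthwaite): the reference
options are residual df N−T (default, the classical multivariate-t choice),
containment df M−T, and infinite (multivariate normal reference).

## Contrast matrices

Each matrix is (T−1)×T with zero-sum rows; row i encodes the candidate
change at position i+1. With per-time-point sample sizes n_j (default:
observed sizes; a balanced flag forces ones):

- **Changepoint**: row i has −n_j/Σ_{k≤i} n_k for j ≤ i and
  +n_j/Σ_{k>i} n_k for j > i (two weighted group means compared).
- **Sequen**: −1 at i, +1 at i+1 (adjacent pairs only).
- **McDermott**: −n_j/Σ_{k≤i} n_k for j ≤ i, exactly +1 at i+1, zeros after.

Sequen localizes a change and gives its direction; McDermott compares each
time point against its whole preceding history and is the recommended
overall-change detector; the Changepoint contrast averages over both sides
of the candidate and, on courses with interior steps, produces biased,
hard-to-interpret pictures — it is provided for completeness.

## Simultaneous inference

With estimates C β̂, covariance S = C vcov(β̂) C' and correlation R, the
equicoordinate two-sided critical value c solves

    P( max_k |T_k| ≤ c ) = 1 − α,   T ~ t_ν(0, R).

Intervals are estimate ± c·se; the single-step (max-t) adjusted p-value of
row k is 1 − P(max_j |T_j| ≤ |t_k|) under the same law.

Numerics: rectangle probabilities use SciPy's randomized-QMC integrator for
the multivariate t (multivariate normal when ν = ∞), default budget 2^17
points, fixed seed; c is found by Brent root-finding on the provable
bracket [univariate two-sided quantile, Bonferroni quantile] with xtol
1e-4. Every probability evaluation inside one call re-seeds the integrator
identically, making the estimated P(c) deterministic and monotone in c, so
the root-finder is stable and the test/interval duality (adjusted p < α iff
the interval excludes 0) holds exactly. The reported `mc_error` is the
standard deviation of the achieved coverage across four re-randomizations;
a warning (not an error) is raised when the 1e-3 coverage tolerance is
missed. Coordinates perfectly (anti)correlated with an earlier one are
removed before integration — they cannot change the maximum.

## Decision layer

- *significant*: the simultaneous interval excludes 0.
- *relevant*: the **entire** interval lies beyond the user's relevance band
  (default ±1 on the log scale; the band must contain 0). Relevance is
  stricter than significance by design — with enough animals, biologically
  trivial effects turn significant. A point-estimate-only mode exists
  behind a flag for exploratory use.
- *direction*: sign of the estimate when significant.
- *overlap_with_previous*: overlap length of consecutive intervals; a
  McDermott row drives an overall-change verdict only when significant and
  (if it has a predecessor) overlapping it by at most `overlap_tolerance`
  (default 0, the strict reading; the tolerance is exposed because "small
  overlap" is a judgment call).
- Sequen rows map to change points at the later time point of the pair;
  successive significant rows with opposite signs raise a fluctuation flag
  (a swing back may be noise or a transient, not two clean change points).

### Maximal usable steps

A planning heuristic for how long a course can get before multiplicity
adjustment swallows even the largest effect: z = δ_max/s, best-case
p_max = Φ(−z) (one-sided default; a two-sided option doubles it), and
Bonferroni caps the usable comparisons at n_max = floor(α/p_max). When the
normal tail underflows double precision (z ≳ 38), n_max is reported as an
order of magnitude computed in log space. The one-sided default follows the
standard worked example of this approximation (δ_max = 3, s = 1 →
p_max = 0.00135, n_max = 37).

## Synthetic data generator

The generator emulates the nested design directly: per time point,
`mothers_per_timepoint` (default 3) mother effects ~ N(0, mother_var = 5);
litter sizes ~ zero-truncated Poisson(λ = 10), sampled by rejection of
zeros (negligible at λ = 10); pup values ~ N(μ_t + u_j, pup_var = 2).
Defaults: T = 12 time points, baseline 20 (keeps raw values positive;
intercept level is otherwise immaterial to the contrasts), step effect 10.
Scenario shapes: flat, steady (linear ± effect over the course), stepwise
(default positions {5,9} for two changes; {7} for one; {4,7,10} for three),
a transient drop of `effect` over block {6,7}, and a dropped-to-zero block
{5..8} carrying exact zeros with no variance (the extreme no-expression
case, which produces a near-singular fit on purpose). One RNG stream per
dataset, fully determined by the spec's seed.

What the generator does **not** emulate: qPCR measurement error and
standard-curve quantification, batch/run effects, unequal spacing of
developmental stages, non-Gaussian endpoints, and gene-gene dependence.
Passing tests therefore demonstrate correct statistical behavior under a
Gaussian nested-cluster model, not robustness to those real-data features.

## Problem sizes and numerical choices in the test suite

The distribution-level checks use 500 replicates for familywise error under
the null (observed 0.078 at the fixed seed set, inside 0.05 ± 3 binomial
SE; the mild liberality is the known price of plugging in estimated
variance components with residual df), 200 replicates for variance-component
recovery (means 4.97 / 2.00 against truths 5 / 2) and for power at the
two-step scenario (both positions found in 98% of replicates; mean step
estimates within Monte-Carlo error of 10). Simulation loops pass a QMC
budget of 2^12–2^13 points per probability — coverage error ~1e-3, well
below the tolerances asserted — while single analyses use the 2^17 default.

## Known limitations

- One gene per run; one random intercept (no slopes, no crossed effects,
  no extra fixed covariates yet — the design matrix construction would
  extend, the profiled one-dimensional REML would not).
- Gaussian endpoints only; use a log transform to approximate normality.
- Residual df is a convention, not an estimate; for few clusters the
  containment option is the conservative alternative.
- The familywise level is controlled per model/contrast family, not across
  genes; screening hundreds of genes needs an additional layer.
- n_max is a Bonferroni back-of-envelope bound, deliberately cruder than
  the multivariate adjustment used for the intervals themselves.
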