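# Methods

## Model class and parameterization

All models are expressed in an all-y LISREL form. Observed abundances
y (p-vector, log-like continuous scale) load on latent variables η
(m-vector):

    y = Λ η + ε,     ε ~ N(0, Θ),  Θ diagonal
    η = B η + ζ,     ζ ~ N(0, Ψ)

Every observed variable that is not an indicator of a declared latent is
given a *pass-through* latent: loading fixed to 1, measurement error fixed
to 0. This lets pure path models (all variables observed) and
latent-variable models share one parameter vector, one implied-covariance
routine, one optimizer, and one Gibbs sampler. Declared latents are scaled
by fixing their first indicator's loading to 1. The implied covariance is

    Σ(θ) = Λ (I − B)⁻¹ Ψ (I − B)⁻ᵀ Λᵀ + Θ.

Free parameters are named in the common SEM text convention (`y~x` path,
`f=~ind` loading, `a~~b` (co)variance) and collected in a fixed-order map,
which is the shared currency of the ML and Bayesian stages. Mean
structures are not modelled; the ML stage fits the covariance matrix and
the Gibbs sampler centers the data columns, which is equivalent to
profiling out unrestricted means.

## Prior-graph construction

A 2DE/MS spot record carries a mass (kDa) and sequence evidence: either a
set of matched peptides or a set of half-open residue intervals
[start, end) in 0-based coordinates on a named reference subunit (one
convention, used everywhere). Containment is evidence-subset: peptide sets
by inclusion (comparable across records, since shared peptides are
themselves the evidence of shared sequence), interval sets by coverage on
the same reference. Comparing a peptide set against an interval set is
meaningless and raises an error rather than returning false; the graph
builder skips such pairs, since a record set may legitimately mix both
kinds across protein families.

A candidate degradation edge heavy → light is created for every comparable
pair where the lighter record is a fragment, its evidence is contained in
the heavier record's, and the mass strictly decreases. Because containment
is transitive, a secondary product nested in a primary product is also
nested in the intact subunit; the builder therefore removes transitively
implied edges, so each product attaches to its *immediate* precursor —
this is the stepwise-pathway reading of the evidence, and it is what makes
"primary" and "secondary" products distinct tiers in the graph rather than
a clique. A fragment contained in several mutually non-nested parents
keeps one edge per parent (the "and/or" case). Mutual containment at equal
mass has no consistent direction and is an error naming the pair.
Regulation edges are user-supplied literature annotations, appended
verbatim; they are the only place self-loops may appear.

## ML estimation

The discrepancy F(θ) = ln|Σ| + tr(SΣ⁻¹) − ln|S| − p is minimized by
L-BFGS-B with an analytic gradient (dF = tr[(Σ⁻¹ − Σ⁻¹SΣ⁻¹)dΣ] reduced to
closed-form entries per slot type). Outside the admissible region (Σ not
positive definite or I−B singular) the objective returns a large penalty;
because that discontinuity can abort an L-BFGS-B line search near the
boundary, an unsuccessful run is restarted from its terminal point (up to
twice) and a terminal point is accepted as converged when its gradient
norm is small. Starting values: 0.5 for free loadings and paths, observed
variances for variance slots (split between latent and measurement error
for indicators). Non-convergence is flagged on the result, never silent.

S is the unbiased sample covariance (divisor N−1) after listwise deletion;
a zero-variance column is an error naming the column. T = (N−1)·F(θ̂) is
the model χ² with df = p(p+1)/2 − q. Standard errors come from the inverse
numerical Hessian of ((N−1)/2)F at θ̂ (central differences of the analytic
gradient); a singular information matrix falls back to the pseudo-inverse
with a warning. Negative variance estimates (Heywood cases) are flagged.
Models with q > p(p+1)/2 are rejected before optimization.

Fit indices: RMSEA = √(max(T−df,0)/(df(N−1))) with a 90% CI from inverting
the noncentral χ² in its noncentrality λ (lower bound from
P(χ²_df(λ) ≥ T) = 0.05, upper from 0.95, 0 where no admissible λ exists)
and a close-fit p-value P(χ²_df(λ₀) ≥ T) at λ₀ = 0.05²·df·(N−1); SRMR is
the root mean square of correlation-scale residuals over the lower
triangle including the diagonal. Indices are undefined (an explicit error)
for saturated models. Standardized coefficients rescale each path by
√(implied var of source / implied var of target), loadings analogously;
they are invariant to rescaling any observed variable.

## Model search

Collinearity detection runs once, before pruning: connected components of
the graph on observed variables with |Pearson r| > 0.9 (the threshold is
configurable; 0.9 is the working default for "near identical expression").
Each group is collapsed into a latent the members indicate; structural
paths touching a member re-attach to the latent, duplicates merged.

Pruning is backward, one path at a time: after each fit, the structural
path with the largest Wald p ≥ α (default 0.05) is removed and the model
refit; the loop stops when every path is significant. Single-step removal
with refitting is the standard safeguard against joint-significance
artefacts; a batch mode (remove all non-significant paths at once) is
available behind a flag. Pruning strictly decreases q, so the loop
terminates in at most q steps. If removal leaves an endogenous variable
with no predictors it simply becomes exogenous (free variance), logged in
the trace.

Structural self-loops are removed deterministically before the first fit
and logged. With a single error-free indicator, a loop coefficient c only
enters Σ through b/(1−c) and ψ/(1−c)², so it is not identified; fitting it
would hand the Wald loop a singular information matrix. Self-loops remain
representable in B for specification and simulation.

The whole search is deterministic given the data, and the trace (collapse,
prune, stop steps with fit indices after each refit) replays to the final
model.

## Bayesian estimation

The selected model is re-estimated by data-augmentation Gibbs sampling,
requiring a recursive B (cycles are rejected with guidance to prune them)
and diagonal Ψ. Each sweep:

1. draws the stochastic latents per sample from their multivariate-normal
   conditional given y (pass-through latents equal their observed variable
   and are never resampled);
2. draws loadings and structural paths per equation from conjugate normal
   conditionals;
3. draws measurement and residual variances from conjugate inverse-gamma
   conditionals.

Priors are weakly informative conjugate defaults: N(0, 10²) on loadings
and paths, IG(0.001, 0.001) on variances. These are this package's
documented choices, selected to keep every conditional closed-form while
contributing negligible information at the study scale. Defaults: 4 chains
of 20,000 iterations, burn-in half the chain, chain k started at the ML
estimate plus a k-dependent offset of up to ±3 SE (overdispersed starts,
so the convergence diagnostic is meaningful). Draws are bit-identical for
a fixed seed and configuration.

Convergence: per parameter, with m chains of length n, W = mean
within-chain variance, B = n × variance of chain means,
V̂ = ((n−1)/n)W + B/n, psrf = √(V̂/W) — the basic Gelman-Rubin form,
without the sampling-variability degrees-of-freedom correction. The
multivariate statistic is √((n−1)/n + ((m+1)/m)λ₁) with λ₁ the largest
eigenvalue of W_pooled⁻¹(B_matrix/n). Zero within-chain variance is an
error naming the parameter. Posterior summaries (mean, sd, 95% equal-tail
interval) pool post-burn-in draws; standardized-coefficient summaries are
computed per draw (thinned to ~4000 draws for the transform) and then
summarized.

Posterior means of structural paths and loadings agree with the ML
estimates within Monte-Carlo error at moderate n under these diffuse
priors. Variance parameters do not, by construction: their marginal
posteriors are skewed, so the posterior mean sits above the ML point
estimate at O(1/n) regardless of chain length. Cross-validation of the two
estimation routes is therefore asserted on paths and loadings.

## Synthetic data and fixtures

The generator draws ζ ~ N(0, Ψ), solves η = (I−B)⁻¹ζ, and emits
y = Λη + ε — exactly the model class the estimators assume, which is the
point: it isolates the statistical machinery from measurement artefacts.
It does *not* emulate 2DE spot-detection noise, censoring of
low-abundance spots, normalisation artefacts, or temporal autocorrelation;
passing tests certify the inference machinery, not robustness to those
real-data features. The default sample size is 48, the scale of the
pooled three-timepoint wheat-leaf study this package targets, so
small-sample behaviours (mediocre RMSEA, wide intervals) are exercised
realistically. Samples are exchangeable by default — the successful
(static) analysis pooled time points; a `time_blocks` option appends a
balanced label column without changing the draws. Whether the original 48
samples were truly exchangeable across the time series is unknowable from
the published record; the generator's default assumes they were.

Two Rubisco fixtures are documented constants of this package (the
original spot-level data were never deposited, so true coefficients are
implementation choices, not published estimates):

* **prior** — the 10-spot hypothesis skeleton: degradation paths
  RLS2→{dp39, dp12, dp37}, {RSS174, RSS175}→dp44, dp39→{dp7, dp15, dp17},
  regulation RSS→RLS2 and a weak RLS2 self-loop, and a planted 0.95
  covariance between the small-subunit spots.
* **final** — the post-search structure: latent RSS (indicators RSS174,
  RSS175, measurement error 0.05 → implied r ≈ 0.952) and latent dplat
  (dp15, dp17, error 0.08 → r ≈ 0.926), paths RSS→{RLS2, dp39, dp12,
  dp37}, RLS2→dp44, dp39→dp7, dp39→dplat. All latent-level variances are
  1, so each structural coefficient equals its standardized value; values
  lie in [0.5, 0.8] (0.5–0.75), with residual variances 1 − coef².

The fragment fixture plants interval evidence for the RLS2 family (the
secondary products sit in coverage gaps of dp37, so transitive reduction
leaves exactly the intended immediate-precursor edges) and peptide
evidence for the small-subunit family (dp44's peptides shared by both
intact spots). A seed jitters masses and secondary-interval bounds within
margins that preserve the containment structure.

## Problem sizes used in the test suite

Consistency checks run at n = 5000 (coefficient recovery within ±0.05,
search-structure agreement over 50 seeds), calibration checks at the study
scale n = 48 (Wald interval coverage over 200 replicates) and n = 100
(pruning type-I error over 500 replicates), Monte-Carlo covariance
validation at n = 10⁵–10⁶, and the convergence reproduction at the full
4 × 20,000-iteration MCMC condition on n = 48. These sizes were chosen so
each check's sampling error is small relative to its tolerance.

## Known limitations

* No mean structures, no GLS/WLS/robust estimators, no multi-group SEM,
  no modification indices, no forward selection: the search only removes
  paths from the prior skeleton, so structure outside the prior cannot be
  discovered — by design, the prior graph is the hypothesis.
* Nonrecursive models are representable and can be fit by ML, but the
  Gibbs sampler rejects them; the search removes self-loops as
  unidentified.
* Gibbs sampling supports diagonal Ψ; correlated residuals must instead be
  expressed as latents.
* Missing data are handled by listwise deletion only.
* The time-resolved variant (one node per protein per time step) is out of
  scope; the generator's block labels are a covariate convenience, not a
  dynamic model.
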