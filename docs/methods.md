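# Methods

## Data-generating model

The population model is a standardized partial-mediation system

    M1 = 0.2 X + e1,   M2 = 0.2 X + e2,   eta = b_xy X + 0.2 M1 + 0.2 M2 + e,

with cov(e1, e2) chosen so the *total* mediator correlation is 0.20
(residual covariance 0.20 − 0.2·0.2 = 0.16), b_xy ∈ {0, 0.2}, and the
structural outcome eta rescaled to unit variance.  The outcome is measured
by p ∈ {3, 9} indicators I_i = λ_i·eta + ε_i with residual variances
1 − λ_i², so the implied (3+p)-variable moment matrix is a correlation
matrix.  Loadings follow a three-value pattern around a base of 0.30 or
0.70 — [λ, λ, λ], [λ−0.10, λ, λ+0.10] or [λ−0.20, λ, λ+0.20] — repeated
three times when p = 9.  With all structural correlations with eta equal
to 0.28 (when b_xy = 0.2), two dependent effect sizes r(V, I_i), r(V, I_j)
have an asymptotic sampling correlation of 0.475 at λ = 0.70 and 0.086 at
λ = 0.30, computed from the Olkin–Siotani covariance of two overlapping
Pearson correlations; the disparity patterns spread these to
[0.406, 0.544] (±0.10) and [0.338, 0.615] (±0.20).

Both the implied-matrix construction and the dependency correlation are
checked in the tests against brute-force simulation of the structural
equations.

## What the simulator emulates

One replication draws k ∈ {20, 60, 100} studies:

1. **Sample sizes** from a lognormal with log-mean 5.13 and log-sd 0.38
   (median ≈ 169, mean ≈ 182, the size distribution typical of social- and
   behavioral-science meta-analyses), rounded, floored at 10.
2. **Between-study heterogeneity**: each unique off-diagonal element of the
   implied matrix is perturbed by an independent normal deviate (diagonal
   T²).  Equal structure: variance 0.01 everywhere.  Unequal structure:
   the anchor–indicator elements alternate 0.01/0.03 over indicators,
   starting at 0.01, so each Y-cell mixes both heterogeneity levels; all
   other elements keep 0.01.  Draws are rejected until positive definite
   (cap 100); rejection rather than projection keeps the marginal element
   variances at their nominal values except for the rare rejections.
3. **Sampling**: one Pearson correlation matrix from n multivariate-normal
   observations per study (no Wishart shortcut, so the finite-sample
   distribution of r is exact).
4. **Dependency pattern**: indicator–indicator correlations are discarded;
   anchor–indicator correlations become the dependent records of the three
   Y-cells.  Studies are assigned to report-count bins by exact
   largest-remainder counts, then randomly permuted: for p = 3, 30% report
   one effect per Y-cell, 35% two, 35% three (k = 20 → 6/7/7); for p = 9,
   30% report one, then seven 10% bins report {2 or 3}, 4, 5, 6, 7, 8, 9
   (the {2 or 3} bin draws either value with probability ½ per study).  The
   retained indicators are a sorted uniform subset, shared by the three
   Y-cells within a study.
5. **Missingness**: 15% of the records in the three non-Y cells are deleted
   at random across studies; Y-cell records are never deleted, so no study
   is ever empty.

The generator reproduces the *design* of real meta-analytic data but not
all of its features: effect sizes are exactly normal-theory Pearson
correlations, dependency exists only for the outcome variable, indicators
are fixed across studies, and missingness is completely at random.
Passing tests therefore demonstrate correctness of the estimators under
the stated model, not robustness to non-normality, selective reporting, or
informative missingness.

## Strategies

Per (study, Y-cell): `simple_average` (arithmetic mean), `weighted_average`
(weights 1/v, v = (1 − r²)²/(n − 1); since all records of a study share n,
the weights differ only through r, which pulls the aggregate toward larger
|r|), `random_select` (uniform), `largest_select` (largest signed value,
ties to the lowest effect id), `ignore` (each row of the within-study
effect table becomes a pseudo-study; non-Y cells only in the first row),
and `wpl` (no reduction; see below).  Selection and aggregation operate
per cell, so a study may keep different effect ids in different Y-cells.

## Stage 1: multivariate random-effects pooling

Observed (possibly incomplete) correlation vectors are modeled as
r_j ~ N(X_j ρ, X_j T² X_j′ + V_j) with diagonal T² and V_j from the
Olkin–Siotani forms divided by n_j − 1, evaluated at the study's own
correlations (missing cells filled with first-pass unweighted cell means).
The likelihood is maximized by profiling ρ out via GLS and optimizing the
six τ² elements with L-BFGS-B under box constraints [0, 1], using the
analytic profile gradient ½Σ_j[(S_j⁻¹)_cc − (S_j⁻¹e_j)_c²]; studies are
grouped by observation pattern and the per-group linear algebra is batched.
Starting values: ρ from unweighted cell means, τ² = 0.01; convergence is
scipy's L-BFGS-B success with gradient tolerance 10⁻⁸; on failure the fit
restarts up to 10 times from |0.01 + N(0, 0.05)| jitter, and a fit that
still fails is flagged (status 2) rather than raised.  The asymptotic
covariance is A = (Σ_j X_j′(T̂² + V_j)⁻¹X_j)⁻¹.  The implementation matches
R's metafor `rma.mv(..., struct="DIAG", method="ML")` to ~10⁻⁵ on test
fixtures.

## Stage 1, WPL variant

All records enter a three-level mixed-effects meta-regression on six cell
dummies with no intercept: random study intercepts (σ²_study) and random
effect-within-study intercepts (σ²_effect), each *shared across cells*, and
known sampling variances v = (1 − r²)²/(n − 1).  The marginal covariance of
a study is diagonal-plus-rank-one, so REML is evaluated with the
Sherman–Morrison identity.  The two variance components are REML-estimated
(L-BFGS-B, bounds [0, 1], 10 jittered restarts); fixed effects use the
prescribed sample-size weights, γ = (X′WX)⁻¹X′Wr with W = diag(n) —
i.e. n-weighted cell means — and cov(γ) is the sandwich
(X′WX)⁻¹X′W M W X(X′WX)⁻¹ at the REML components.  A configuration switch
(`weighting="inverse_variance"`) replaces W with M⁻¹, giving the GLS
estimate with cov (X′M⁻¹X)⁻¹; this mode matches metafor's three-level
`rma.mv` REML fit and is used for cross-validation.  Treating the sampling
variances as known (rather than estimating a free residual variance) is
the standard three-level meta-analytic convention and was chosen where the
original description is ambiguous; the alternative is a one-line change in
the variance construction.

## Stage 2: WLS path fit

F(θ) = (r − r_MODEL(θ))′A⁻¹(r − r_MODEL(θ)) is minimized by
Levenberg–Marquardt on Cholesky-whitened residuals with the analytic model
Jacobian, from a fixed neutral start (paths 0.1, ψ 0.05) with up to 10
jittered restarts; A is inverted with an escalating ridge (10⁻¹⁰…10⁻⁶) if
ill-conditioned.  The model is just identified, so F < 10⁻⁸ at any valid
solution and the estimates coincide with the closed-form regression
solution (tested to 10⁻⁶).  Standard errors come from (J′A⁻¹J)⁻¹, Wald
z = θ̂/se, and 95% CIs are θ̂ ± 1.96·se.

## Evaluation truth: attenuated pseudo-true values

The fitted 4-variable model observes Y only through its indicators, so the
population value of a pooled Y-cell correlation is the mean
anchor–indicator correlation, λ̄·ρ(V, eta).  Fitting the path model to this
collapsed average population matrix gives the pseudo-true parameters the
consistent strategies estimate: X → M paths 0.20, mediator residual
covariance 0.16, Y-paths λ̄ × 0.2 (0.14 at λ = 0.70, 0.06 at λ = 0.30), and
exactly 0 when the population X → Y path is 0.  All bias, RMSE, coverage
and rejection metrics use these values (`pseudo_true_paths`); judging the
Y-paths against the unattenuated 0.2 would misattribute the measurement
attenuation — identical for every strategy — as estimation bias.

## Metrics

Relative bias 100(mean θ̂ − θ)/θ (NaN at θ = 0); absolute bias; relative SE
bias 100(mean SE − SD)/SD with SD the (n−1)-denominator standard deviation
of estimates; RMSE² = (mean θ̂ − θ)² + population variance of θ̂ (the
decomposition identity is asserted to 10⁻¹²); coverage of the 95% Wald CI;
rejection rate (|z| > 1.96), read as power when θ ≠ 0 and as the
false-positive rate when θ = 0.  Non-converged replications are excluded
and counted.  `mc_interval` gives the normal-approximation Monte-Carlo
band for an observed proportion ([0.936, 0.964] for 0.95 at 1,000
replications).

## Problem sizes

The full design is 144 conditions × 1,000 replications; the package runs
any subset at any replication count.  The bundled test suite and the
acceptance script reproduce the headline contrasts at desk scale —
250–300 replications on the design cells where the effects concentrate
(p = 9, λ = 0.70 for the standard-error results; the zero-path cells for
false positives; k = 100 cells for convergence) — which leaves Monte-Carlo
noise of roughly ±4 percentage points on an SE-bias estimate and ±2 points
on a rejection rate; max/min statistics are taken over several cells, as in
the full-scale study.  Seeds derive from SeedSequence(master, crc32
(condition id), replication), so every cell is independently reproducible
and results do not depend on worker count.

## Known limitations

- The unequal-T² assignment (which Y-cell elements get 0.03) is an
  alternating stand-in; results may be mildly sensitive to the true
  pattern, which is configurable via `Tau2Spec`.
- Sampling variances inside the WPL model are treated as known; a free
  residual variance is a documented alternative.
- Only correlation (not covariance) matrices are generated; loadings must
  lie in (0, 1); no moderators, no hierarchical (same-lab) dependence, no
  robust variance corrections.
- Stage 1 constrains T² diagonal, matching the generator; a full T² is out
  of scope.
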