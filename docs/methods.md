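# Methods

This note records the statistical model, the estimation algorithms, the
numerical choices, and the limits of what the package's tests demonstrate.

## Generative model

Counts for gene *g*, subject *i*, observation *j*:

    Y_gij ~ NB(mu_gij, alpha_g),  Var(Y_gij) = mu_gij + alpha_g * mu_gij^2
    log mu_gij = x_ij' beta_g + b_gi,   b_gi ~ N(0, sigma2_g)

The fixed-effect design is reference-coded: intercept, treatment indicator,
timepoint-2..4 indicators, and the three group-by-time interactions (eight
coefficients for the default four timepoints). The subject random intercept
induces a compound-symmetric (exchangeable) within-subject correlation on
the log scale; time-decaying correlation structures are deliberately out of
scope.

### Surrogate parameter distribution

Realistic simulations need joint draws of (mean CPM, dispersion alpha,
random-intercept variance sigma2_b). Empirical triplet tables from real
repeated-measures cohorts can be supplied as a TSV
(`SurrogateParamDistribution(triplets=...)`, resampled with replacement).
The built-in parametric surrogate is used when none is given:

* log2 mean-CPM ~ Normal(3, 2^2), truncated below at CPM = 0.1 — a typical
  bulk RNA-seq expression spread;
* alpha = (0.05 + 2 / mean_count) * LogNormal(0, 0.4^2) — the standard
  mean–dispersion decay (Poisson-like noise dominating at low counts,
  biological CV^2 ~ 5% asymptotically) with gene-level scatter;
* sigma2_b ~ LogNormal(log 0.2, 0.8^2) — between-subject log-scale
  variances giving within-subject ICCs in the ranges seen in human cohort
  data.

The intercept follows the benchmark's construction: drawn CPMs are rescaled
to sum to one million and multiplied by a 25-million total library size;
beta_0 is the log of the resulting expected count. A consequence worth
knowing: at reduced gene counts (e.g. 2,000 instead of ~15,000) the
rescaling concentrates the same library onto fewer genes, so per-gene means
are proportionally higher than in a full-scale run. Effect sizes are planted
in a configurable fraction of genes (default 20%) as (|b5|, |b6|, |b7|) =
(1/3, 2/3, 1) with one Rademacher sign per gene shared across the three
effects (keeping each DE gene's time trend monotone); independent signs per
effect are available via `effect_sign_rule="independent"`.

NB sampling uses the size/probability parameterization with size = 1/alpha;
alpha = 0 falls back to exact Poisson draws. Linear predictors above 30 are
clipped and the gene is recorded in `CountMatrix.overflow_genes` rather than
crashing the replicate. Expression filtering keeps genes exceeding 1 CPM in
at least `n_per_group` samples (the size of one group to timepoint cell),
computed against unfiltered library sizes, and runs once per dataset before
any normalization or fitting.

## Normalization and the VST

Size factors are median-of-ratios: each sample's factor is the median over
all-positive-count genes of the ratio to the gene's geometric mean, then
rescaled to geometric mean one. They enter the count models as log offsets.

The dispersion trend alpha(mu) = a0 + a1/mu is fitted by regressing
per-gene method-of-moments dispersion estimates on 1/mu with Huber robust
least squares; negative components are clipped (a0 floor 1e-8). The
variance-stabilizing transform integrates 1/sqrt(mu + alpha(mu) mu^2) in
closed form:

    vst(x) = (2 / ln 2) * asinh( sqrt( a0 * x / (1 + a1) ) )

applied to size-factor-normalized counts; it is monotone and approaches
log2(x) + const for large x. On data whose variance includes a
between-subject component the fitted trend absorbs that extra variance into
(a0, a1); the transform remains a monotone stabilizer, which is all the LMM
route requires. `log2(normalized + 0.5)` is available as a fallback
(`transform="log2"`).

## Estimation

### LMM by profiled REML

For transformed data y = X beta + Z b + eps with b ~ N(0, sigma2_b I) and
eps ~ N(0, sigma2_e W^-1) (W = known weights, identity for the plain LMM),
the REML criterion is profiled over the variance ratio
lambda = sigma2_b / sigma2_e. Each subject's covariance block is compound
symmetric, so its inverse and determinant are closed-form (Woodbury / matrix
determinant lemma), making one criterion evaluation O(N p^2). The scalar
optimization uses bounded Brent on log lambda over [-13, 13], with the
lambda = 0 boundary checked explicitly. A fit is flagged *singular* when the
ICC lambda/(1+lambda) < 1e-6 (boundary fit); a constant response is flagged
non-converged. The implementation agrees with independent REML software to
six decimals on coefficients, variance components and the restricted
log-likelihood (see `tests/test_lmm.py`).

### Satterthwaite denominator degrees of freedom

The variance-parameter covariance is the inverse of half the numerically
differentiated Hessian of the -2 restricted log-likelihood in
(sigma2_b, sigma2_e) (central differences, relative step 1e-4; one-sided at
the zero boundary). For a single contrast l, DF = 2 f^2 / Var(f) with
f = l' C(theta) l and Var(f) by the delta method. Multi-row contrasts use
the eigen-decomposition of L C L': per-eigenvector one-dimensional DFs
nu_m are combined through E = sum nu_m/(nu_m - 2) (over nu_m > 2) and
DF = 2E/(E - q). Fallbacks: singular fits, non-PSD variance-parameter
covariance, or E <= q all yield the OLS residual DF (N - p). In a balanced
design the time-averaged group contrast reproduces the classical
n_subjects - 2 exactly, and a paired-design within contrast reproduces the
paired-t DF of n - 1 — both verified in tests.

### NB mixed model by adaptive Gauss–Hermite quadrature

The marginal likelihood integrates the subject random intercept
numerically: for each subject the integrand's mode is found by a damped,
vectorized 1-D Newton iteration (the joint log-density is strictly concave
in b), the local curvature sets the quadrature scale, and Gauss–Hermite
nodes (default 11) are recentred and rescaled there. One node reproduces
the Laplace approximation, which is how the Laplace variant is exposed
(`n_nodes=1`). sigma2_b = 0 reduces exactly to the NB GLM likelihood.

Maximization is quasi-Newton (L-BFGS-B) over (beta, log alpha,
log sigma2_b), bounds log alpha in [-12, 8] and log sigma2_b in [-23, 5].
The score is computed through the Fisher identity — the posterior
expectation of the joint-likelihood score, evaluated under the same
quadrature rule — which is exact in the quadrature limit and accurate to
~1e-5 at 11 nodes. Starting values: a step-halving Newton Poisson GLM for
beta, Pearson moment estimate for alpha, between-subject variance of mean
working residuals for sigma2_b. The coefficient covariance (when requested)
is the inverse observed information obtained by differencing the score.
Singularity: sigma2_b below 1e-8 or at its bound. Reduced models for LRTs
are built by reparameterizing the design so contrast rows become leading
coefficients that are dropped (see Testing below); a reduced-model fit
failure makes that gene's test non-computable rather than silently dropped.

### NB mixed model by pseudo-likelihood

Iterates three steps to joint convergence (relative change in (beta,
sigma2_b, alpha) below 1e-8, cap 200 outer iterations):

1. working response z = eta + (y - mu)/mu and weights w = mu/(1 + alpha mu)
   at the current conditional mean (including the subject BLUPs);
2. weighted REML LMM for (beta, sigma2_b) with the profiled solver above;
3. Pearson chi-square dispersion update: alpha solves
   sum (y - mu)^2 / (mu (1 + alpha mu)) = N - p by Brent root-finding
   (floored at 1e-8 when the counts are underdispersed, capped at 100).

The final weighted LMM supplies the coefficient covariance and the
variance-parameter information, so the same Satterthwaite F machinery
applies to this fitter — the reason this estimation route pairs with F
tests rather than LRTs (its objective is not a true likelihood). The
Pearson update is this package's documented choice of dispersion step.

### GEE

Marginal Poisson-scale model (variance phi * mu), log link, exchangeable
working correlation. The estimating equations are solved by IRLS-type
updates with moment re-estimation of phi (Pearson chi-square / (N - p)) and
rho (average within-subject cross-product of Pearson residuals, clipped to
the valid exchangeable range); the closed-form inverse of the exchangeable
correlation keeps every update O(N p). Coefficients are invariant to phi
and to the covariance estimator choice. Three covariances are provided:

* naive (model-based) A^-1;
* robust sandwich A^-1 M A^-1 with per-subject score outer products;
* Wang–Long small-sample corrected (default for testing): per-subject
  residuals are inflated by the cluster-leverage factor (I - H_i)^-1 and
  their standardized cross-products pooled across subjects before being
  re-expanded to each subject's scale — countering the downward bias and
  instability of the plain sandwich when subjects are few. Pooling requires
  a common cluster size; unequal clusters fall back to the unpooled
  bias-corrected form with a warning. The corrected and plain sandwiches
  estimate the same limit; their agreement at large subject counts is
  checked on totals (traces) because individual elements converge slowly
  under heavy-tailed overdispersion.

## Testing

Contrast matrices over (b0..b7): between rows {e1, e1+e5, e1+e6, e1+e7}
(rank 4); within rows {e2+e5, e3+e6, e4+e7} (rank 3 — the pairwise
differences sometimes listed with this hypothesis are linear combinations,
and Wald/F machinery requires full row rank); interaction {e5, e6, e7};
global {e1..e7}. The within test defaults to the treatment group's time
profile; `within_group="reference"` tests the control group's instead.

Wald chi-square: W = (L b)' (L V L')^-1 (L b), p from chi2 with rank(L) DF;
a singular contrast covariance falls back to the pseudo-inverse with the
matrix rank as DF. F tests divide W by the rank and use Satterthwaite
denominator DF. LRTs clip the statistic at zero and warn if the reduced
log-likelihood exceeds the full one by more than 1e-6 (an optimization
failure, not evidence). BH adjustment is applied per test across genes,
never pooled across tests; non-computable genes are excluded and reinserted
as missing. (BH is monotone and order-preserving but not idempotent — a
second application can change values — so only the former are asserted as
invariants.)

## Evaluation metrics

Empirical FDR = FP / max(1, declared positives) — zero declarations give
FDR 0 by convention. Power = TP / (truth-DE genes among computable).
Genes whose model did not converge are excluded from both numerators and
denominators and reported through the convergence rates instead: the
full-model failure rate, and separately the fraction of genes whose full
model converged but at least one LRT reduced model failed. Metrics are
averaged arithmetically across replicate datasets.

Profile clustering: fixed-effect predicted expression at each timepoint
(random intercept zero), rows centred/scaled, correlation distance
(1 - Pearson r), complete linkage, tree cut at a user-chosen k (default 7).
Constant profiles have undefined correlation and are dropped with label 0.

## Problem sizes and reproducibility

The package's own benchmark runs (acceptance script and the heavier tests)
use 3 replicates x 2,000 genes at 10 subjects per group — a deliberate
desk-scale choice that preserves the benchmark's qualitative behavior
(anti-conservative GEE and quadrature-NBMM FDR, controlled LMM FDR with
high power, near-uniform LMM null p-values) while completing in minutes.
One master seed drives a SeedSequence tree spawning per-replicate and
per-stage substreams, so results are independent of evaluation order; rerun
with the same seed is bit-identical.

## What the synthetic benchmark does and does not show

The generator matches the model the fitters assume (NB margins, a single
compound-symmetric random intercept, common library sizes, independent
genes). Real repeated-measures data add serially decaying correlation,
library-size variation, gene–gene correlation, outlier samples and
composition effects — none of which are simulated, so passing benchmarks
here demonstrate correctness of the machinery and calibration under the
stated model, not robustness to those violations. The LMM route's
calibration additionally depends on the VST delivering approximate
variance stabilization, which degrades for very low counts.

Known limitations: a single variance component (no random slopes); no
time-decaying (AR-type) working correlation; no moderated/empirical-Bayes
shrinkage; LRT inference for the quadrature NBMM relies on the asymptotic
chi-square, which is visibly anti-conservative at small subject counts —
reproducing that behavior is part of the package's purpose, not a defect.
At ten subjects per group the sampling floor of the interaction-coefficient
error (median absolute error ~0.674 * sqrt(4 alpha / n_per_group)) is
~0.11 under the default parameter distribution; recovery checks should be
read against that bound.
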