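# Methods

## Model

gsemkit fits multivariate AE variance-component models to t traits measured
on n nominally unrelated, genotyped individuals. Additive-genetic latent
factors are "tagged" by a genome-wide genetic relationship matrix (GRM):
for individuals j, k and SNPs i with reference-allele frequency p_i,

    A_jk = (1/M_jk) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i)),

summed over SNPs observed in both individuals (M_jk of them, the
pairwise-complete convention of the GCTA binary `.grm.N.bin` companion
file). Allele frequencies are taken from the sample itself (non-missing
column mean / 2) unless supplied; monomorphic SNPs are excluded, since the
standardization denominator vanishes. The estimator uses the standard
(non-inbred) diagonal formula. Under the model

    cov(vec(Y)) = Σ_g ⊗ A + Σ_e ⊗ I_n,

with Σ_g = Λ_a Λ_aᵀ and Σ_e = Λ_e Λ_eᵀ implied by the loading patterns of a
`ModelSpec`. All latent factors have unit variance, so free parameters are
loadings only. The assumptions are the usual ones for GRM-based variance
components: additivity (no dominance or shared-environment term — an AE,
not ACE, decomposition), multivariate normal residuals, unrelated
individuals (the package implements the customary greedy pruning at
pairwise relatedness > 0.025), and complete cases across all modelled
traits (missing-data FIML over incomplete trait vectors is out of scope).

Because phenotypes are expected to be residualized and rank-transformed
before modelling, the mean structure is fixed at zero. This also explains
why ML estimates here track REML closely: with no estimated fixed effects
the two likelihoods differ only by a constant profile term.

## Likelihood evaluation

The n·t-dimensional likelihood factorizes after rotation onto the GRM
eigenbasis. With A = U diag(d) Uᵀ and Ỹ = UᵀY, the rows of Ỹ are
independent, row i having covariance Ω_i = d_i Σ_g + Σ_e, giving

    −2 log L = Σ_i [ t log 2π + log|Ω_i| + ỹ_iᵀ Ω_i⁻¹ ỹ_i ].

The implementation evaluates all n small t×t Cholesky factorizations in a
single batched call; any non-positive-definite Ω_i yields +∞ (a penalty,
not an error), which in practice only occurs when the residual covariance
collapses. The rotated form is validated in the test suite against a dense
−2 log MVN(vec(Y); 0, Σ_g ⊗ A + Σ_e ⊗ I) evaluation at n ≤ 60, t ≤ 4
(tolerance 1e-6) — the core correctness oracle of the package.

## Optimization and standard errors

Parameters are unconstrained loadings (the factor parameterization keeps
Σ_g, Σ_e positive semidefinite for any real θ). Optimization is L-BFGS-B
with numerically approximated gradients and three default starts: (i) a
structure-aware split of the sample covariance S into equal genetic and
residual halves (for triangular structures, Cholesky factors of S/2);
(ii) the same with a near-zero genetic share (5%); (iii) a seeded random
perturbation of (i). Convergence uses a relative function tolerance of
1e-10 and gradient tolerance 1e-5 (both configurable); a fit is flagged
`converged` when the optimizer reports success or the scaled gradient norm
is ≤ 1e-4.

Because Σ = LLᵀ is invariant to negating a whole factor column, fitted
loadings are canonicalized post-hoc: any column whose leading free loading
is negative is flipped (for the common pathway model, λ is flipped to a
positive leading loading and f_g, f_e are reported nonnegative). Σ_g and
Σ_e — not individual loadings — are the identified objects.

Standard errors come from the observed information: a central
finite-difference Hessian H of −2LL at θ̂ with per-coordinate steps
1e-4·max(1, |θ_i|), and cov(θ̂) = 2 H⁻¹. If the smallest Hessian eigenvalue
falls below 1e-7 of the largest, the information matrix is treated as
degenerate (a flat ridge, e.g. an identity GRM leaving only Σ_g + Σ_e
identified) and SEs are reported missing with a warning rather than
fabricated from a near-singular inverse. Derived quantities (entries of
Σ_g, Σ_e, genetic correlations, variance-share ratios) get first-order
delta-method SEs with central-difference gradients at step
1e-5·max(1, |θ_i|); the delta SE of the genetic correlation is checked
against a parametric bootstrap (simulate from the fitted model, refit)
within 15% in the test suite.

## Model comparison and stage-II reduction

Nested structures are compared by likelihood-ratio χ² (Δχ² clamped to zero
when negative within 1e-4 optimizer noise; a larger negativity is an
error), AIC = −2LL + 2k and BIC = −2LL + k·log(n) with n the number of
participants, not n·t observations. Variance-component reductions can place
parameters on the boundary of their space, where the χ² reference is only
approximate; a 50:50 χ² mixture reference is available via `lrt(...,
mixture=True)` for sensitivity analysis, with the plain χ² as the default.
Wald tests on loadings use the normal reference, two-sided by default with
a one-tailed option.

The data-driven reduction (`reduce_model`) formalizes stepwise pruning of
genetic structure: repeatedly drop the genetic loading with the smallest
absolute standardized value (ties drop the later trait/factor position,
making the procedure deterministic), refit, and compare with the starting
model by LRT. It stops when every remaining genetic loading is significant
at α (default 0.05), or when a drop would make the cumulative LRT
significant (that drop is rejected). Both the audit trail and the stopping
reason are returned.

## Phenotype preparation

Each trait is adjusted for covariates (sex, age, ancestry principal
components, …) by OLS with an intercept, fitted on jointly observed rows;
rows missing the outcome or any covariate stay missing. Residuals are then
mapped to normal quantiles of their offset-adjusted ranks,
Φ⁻¹((r − c)/(n − 2c + 1)), with Blom's c = 3/8 by default (options: c = 0
and c = 1/2); ties receive average ranks before transformation, which is
deterministic and order-independent. Residualization runs on all samples
with complete covariates *before* the complete-case restriction on the
modelled traits, so each score is adjusted on the largest available sample.

## Synthetic data

The simulator emulates a cohort-style input at desk scale: n up to a few
thousand unrelated individuals, HWE genotypes in linkage equilibrium with
allele frequencies uniform on (0.05, 0.5), and 2–4 standardized traits.
The default design is the validation setting used throughout: a bivariate
standardized trait, n = 5000, 10 replicates, tagged variance fractions 0.25
and 0.45 with genetic correlation 0.5 and residual correlation 0.3 — trait
architectures in the middle of the range reported for longitudinal
social-communication measures (univariate SNP-h² roughly 0.09–0.47). The
m = 5000 simulated SNPs (1000 causal) are a deliberate scale-down from
dense genome-wide panels of several hundred thousand SNPs; at this m the
GRM's off-diagonal noise (SD ≈ 1/√m) still dominates pedigree-free
relatedness, which is the regime the estimator is designed for.

Two phenotype routes are provided and tested against each other. The
*causal* route standardizes a random subset of SNP columns and draws
per-SNP effect vectors β_i ~ MVN(0, Σ_g/m_causal), so the expected tagged
covariance is exactly Σ_g while the GRM must be estimated — the realistic
pipeline. The *GRM* route draws rotated rows directly from
MVN(0, d_iΣ_g + Σ_e) — exactly the fitted model, used for calibration
checks (coverage, Wald type-I error). Negative GRM eigenvalues (possible
when m < n) are clipped to zero in the GRM route, with the clip logged.

What passing simulations do *not* show: robustness to linkage
disequilibrium (none is simulated; the likelihood is agnostic to LD given
the GRM, but GRM construction from LD-structured panels is not exercised),
to ascertainment or attrition, to binary/liability traits, or to cryptic
family structure beyond the pruning threshold.

The accuracy study (`run_accuracy_study`) runs the full pipeline per
replicate — simulate genotypes, estimate the GRM, fit the saturated
model — and reports per-parameter bias, bias², RMSE and MAD across
replicates, excluding (and counting) non-convergent replicates. All
randomness descends from a single design seed via seed substreams, so
reports are bit-reproducible.

## Problem sizes used in the tests

The shipped test suite exercises the same oracles at reduced scale so the
default run stays fast: univariate heritability recovery at n = 1500,
m = 1500, 5 replicates; the accuracy bound (bias² < 10⁻³ on every Σ_g/Σ_e
entry) at n = 2000, m = 2000, 10 replicates; Wald type-I calibration over
200 null replicates at n = 300; stepwise-reduction recovery of a planted
two-factor structure at n = 300 over 2 replicates. `scripts/acceptance.py`
runs the accuracy study at its full n = 5000 × 10-replicate design.

## Numerical notes and limitations

* The GRM is double precision in memory and float32 on disk (the binary
  interchange format is float32); round-trips are exact at float32
  resolution.
* Eigendecomposition of the n × n GRM is the O(n³) step; it is computed
  once and reusable across model fits on the same sample (`fit` accepts a
  precomputed `EigenGRM` or `RotatedData`).
* The common pathway model is fitted in the relaxed parameterization
  (f_g² + f_e² = 1 not imposed) because the constrained form has a singular
  Hessian; only the products f_g·λ_j, f_e·λ_j are identified, and k counts
  the relaxed parameters (3t + 2).
* The greedy relatedness pruning rule (repeatedly drop the individual in
  the most violating pairs, ties dropping the later sample) is a documented
  heuristic; it is verified against exhaustive search on planted-clique
  instances but is not guaranteed maximum-cardinality in general.
* Analytic gradients / AI-REML updates, multiple (partitioned) GRMs, and
  sample sizes where the n × n eigendecomposition is infeasible are out of
  scope.
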