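# Methods

This note documents the statistical models, numerical choices and the
synthetic-data model behind `pedherit`, and states what the package's tests
do and do not demonstrate.

## Pedigrees and kinship

Pedigrees are read from LINKAGE/PLINK-style whitespace-delimited files
(family, individual, father, mother, sex; missing parent `0`; sex 1 = male,
2 = female, 0 = unknown). Validation rejects duplicate ids, parents
unresolvable within the family, ancestry cycles, and single-parent records
(a flag pads a dummy founder instead). Individuals are stored in
topological order (parents before offspring).

Kinship coefficients follow the standard recursion computed in that order:
founders are non-inbred and mutually unrelated (the usual polygenic-model
assumption; no founder genotype information exists to justify anything
richer), φ_ii = ½(1 + φ_father,mother), and
φ_ij = ½(φ_father(i),j + φ_mother(i),j) for earlier j. Because founders are
unrelated, cross-family kinship is exactly zero and 2Φ is block diagonal,
which every downstream likelihood exploits. Relative pairs are summarized
by kinship class (0.25, 0.125, 0.0625, other nonzero). The recursion is
validated in the tests against Monte-Carlo gene dropping (200k allele
drops, agreement within 0.005) and textbook identities.

## Trait preparation

Analysis traits are transformed (none, log, or rank-based inverse-normal)
and then residualized on covariates by OLS. The inverse-normal transform
uses Blom plotting positions, z_i = Φ⁻¹((r_i − 3/8)/(n + ¼)), with average
ranks for ties; the 3/8 offset is the common default. The built-in
covariate vocabulary is {age, sex, age², age×sex, age²×sex} plus any extra
phenotype column (e.g. dietary intake for a diet-adjusted re-analysis);
the default set is {age, sex, age², age×sex}. Age is centered before
powers are formed to reduce collinearity. An optional screening mode
refits keeping only terms with p ≤ 0.10; the default retains all requested
terms, since which "age and sex terms" matter is trait-specific. Missing
data are handled complete-case per trait (per pair for bivariate fits);
the pedigree is always retained in full for kinship. Multiple-testing
correction uses the Benjamini–Hochberg step-up procedure
(statsmodels' implementation behind `bh_fdr`; the test suite checks it
against a from-scratch step-up recursion).

## Univariate polygenic model

The prepared trait y (mean absorbed by residualization) is modelled as
N(0, Ω), Ω = 2Φσ²_g + Iσ²_e. Within each family block, 2Φ = UΛUᵀ is
eigendecomposed once; rotating y by Uᵀ diagonalizes Ω, so with
σ²_p = σ²_g + σ²_e and d_i(h²) = h²λ_i + (1 − h²),

  σ̂²_p(h²) = n⁻¹ Σ ỹ_i²/d_i,  ℓ_profile(h²) = −½[n log(2πσ̂²_p) + Σ log d_i + n].

The ML estimate maximizes this smooth one-dimensional profile: a 101-point
grid on [0, 1] followed by bounded Brent refinement (xatol 1e-8). The grid
dominates any finite multi-start scheme at negligible cost, which is why
multi-start heuristics are not used. ML is the default because the mean is
removed before fitting; REML with respect to an intercept is available
(`reml=True`) and agrees with ML to well under the estimation SE at study
scale.

The SE of ĥ² is the observed-information SE obtained from the curvature of
the profile log-likelihood (quadratic fit over a ±0.02 stencil, one-sided
at the [0, 1] boundary); profiling out σ²_p makes this equivalent to the
delta method on the full information matrix. H₀: σ²_g = 0 lies on the
parameter boundary, so the LRT p-value uses the ½χ²₀:½χ²₁ mixture,
p = ½P(χ²₁ ≥ Λ) with Λ clamped at 0. Identifiability requires at least two
families with two or more phenotyped relatives.

A known property of the constrained estimator, visible in the recovery
simulations: when the true h² lies within a fraction of an SE of 1 (e.g.
0.98 with SE ≈ 0.10), estimates pile up at the boundary, the replicate
mean is pulled down by roughly E[(X−1)⁺] ≈ 0.03 and the replicate SD is
truncation-shrunk to ~0.6× the information SE. The reported SE describes
the curvature of the likelihood, not the SD of the truncated sampling
distribution; both statements are checked, not hidden, in the test suite.

## Bivariate polygenic model

For a pair of prepared traits, Ω = G ⊗ 2Φ + E ⊗ I with
G = [[σ²_g1, ρ_G σ_g1 σ_g2], [·, σ²_g2]] and E analogous with ρ_E. After
the same per-family rotation, the pair of rotated observations at
eigenvalue λ_i has 2×2 covariance λ_i G + E, and the log-likelihood is a
vectorized sum of closed-form 2×2 determinants and quadratic forms.

Parameterization: variances on the log scale, correlations on the
Fisher-z scale (|z| ≤ 7), giving smooth unconstrained optimization with
exact bound enforcement (L-BFGS-B, ftol 1e-12, moment-based starts from
the univariate fits and empirical correlations plus a ρ_G = 0 start).
The fitted ρ_P is derived from the decomposition identity
ρ_P = √(h₁²h₂²)ρ_G + √(e₁²e₂²)ρ_E, so the identity holds to machine
precision by construction. Estimates with |ρ̂| > 0.999 or h² within 1e-4
of {0, 1} carry boundary flags; when σ²_g of either trait is near zero
(small cohorts), ρ_G is weakly identified and can legitimately pin at ±1
with a flag rather than an error.

LRTs for ρ_G = 0, ρ_E = 0 and ρ_P = 0 use constrained refits against a
χ²₁ reference (correlations are interior parameters). The ρ_P = 0
constraint is imposed through the decomposition: ρ_E is eliminated as
−√(h₁²h₂²/e₁²e₂²)·ρ_G, with a quadratic penalty if the implied ρ_E leaves
(−1, 1). If a constrained optimum exceeds the full optimum, Λ is clamped
to 0 (p = 1) with a warning. 95% intervals are Wald on the z scale from a
finite-difference observed information (central differences, step 1e-4),
back-transformed by tanh; the ρ_P interval uses the delta method followed
by a Fisher-z transform. Profile-likelihood intervals were considered and
not implemented: the z-scale Wald intervals are the conventional output
and the tests only require coverage-sanity, not exact interval matching.

## Metabolic indices

PMI = BMI z-score + (WC/WC_ref)·(TG/TG_ref)·(HDL_ref/HDL), with waist in
cm, lipids in mmol/L, and sex/age-stratified references: WC_ref =
36.13 + 2.30·age (girls) or 44.08 + 1.48·age (boys); TG/HDL references
(0.88, 1.32) for girls under 10, (1.04, 1.34) for girls 10 and over,
(0.77, 1.38) and (1.06, 1.30) for boys. Two interpretation decisions:
age exactly 10 joins the older stratum (the strata are defined as "<10"
and ">10", leaving 10 unassigned, so a half-open rule is required), and
the bracket typography around the product term is treated as grouping
rather than the floor function — a floor would make the index
piecewise-constant and destroy its documented correlation behaviour. At
the reference values the product is exactly 1, so PMI = bmi_z + 1; the
index is strictly increasing in waist and TG and decreasing in HDL.

BMI z-scores are accepted as a column, or computed from a user-supplied
LMS reference table (z = ((BMI/M)^L − 1)/(L·S), interpolated linearly in
age within sex); no growth reference is bundled because the appropriate
one (CDC vs national) is population-specific.

HOMA-IR is the standard G₀·I₀/405 (glucose mg/dl, insulin µIU/ml).
Matsuda ISI is the standard 10⁴/√(G₀·I₀·Ḡ·Ī) with the means taken over
all OGTT timepoints including fasting; fasting plus at least two
post-load points are required. Unit conversions: TG mg/dl ÷ 88.57 and
HDL mg/dl ÷ 38.67 to mmol/L, waist mm ÷ 10 to cm.

## Response surfaces

`fit_surface` fits, at each node of a regular grid (default 50×50 spanning
the data range), a quadratic polynomial (1, x, y, x², xy, y²) by weighted
least squares with Gaussian kernel weights exp(−d²/2b²) on z-scored
coordinates, multiplied by optional per-point inverse-variance weights
(default 1: no per-point variance model is assumed). The node prediction
is the local intercept, so an exactly quadratic response is reproduced to
machine precision and the bandwidth → ∞ limit is the global quadratic
fit (both tested). The default bandwidth is 0.5 SD units — the original
smoothing settings of the commercial implementation this emulates are
unpublished, so the defaults are exposed in the config and the testable
claims are qualitative shape contrasts, not node values. Nodes whose Kish
effective sample (Σw)²/Σw² falls below 6 (the quadratic's parameter count)
are computed but flagged unsupported rather than silently extrapolated.

`summarize_surface` averages the fitted surface over the grid rows inside
a PMI band — using only supported nodes and dropping ragged edge columns
with less than half the band rows supported — and classifies the profile
along the carotenoid axis: "no trend" if the profile range is under 15% of
the supported surface's range, otherwise increasing / decreasing /
interior maximum / nonmonotone from the finite-difference sign pattern
(80/20 thresholds) and the argmax position. The band 2–4 is where the
carotenoid–ISI interaction is expected to be most variable, so the
pipeline reports bands [0, 2] and [2, 4] by default.

## Synthetic cohort model

The generator reproduces the design features the estimators rely on, with
every draw flowing from a single seed:

- **Pedigree.** 401 nuclear families; children per family from
  {1:0.55, 2:0.30, 3:0.10, 4:0.04, 5:0.01} (range 1–5, mean 1.66, so the
  expected number of phenotyped children is ≈670 — the family-size mean and
  the cohort size cannot both match their round descriptions at 401
  families, and the cohort size is the binding quantity). With probability
  0.3 a family's mother or father is created as an extra offspring of the
  previous family's couple, chaining sibships into extended families and
  producing avuncular (φ = 0.125) and cousin (φ = 0.0625) pairs among the
  study children; the related-pair total is matched in order of magnitude
  only, as the true pedigree topology of such studies is never published.
  Children's ages are uniform on [6, 17]; the girl fraction is 0.493.
- **Phenotypes.** Study children are the leaf nonfounders. Genetic effects
  are drawn per extended-family block from MVN(0, G ⊗ 2Φ) via eigenvalue
  square roots, environmental effects iid MVN(0, E), with
  G = D_h ρ_G D_h, E = D_e ρ_E D_e (D_h = diag(√h²)), so each latent trait
  has unit variance and additive fraction exactly h². The entrywise
  decomposition-implied phenotypic correlation matrix must be PSD or
  generation refuses. Observed traits are mean + sd·latent (identity) or a
  log-normal with matching observed mean and SD (for right-skewed analytes
  — carotenoids, triglycerides, insulin — whose SDs approach or exceed
  their means); small age/sex effects enter on the latent scale.
- **OGTT.** Fasting glucose is log-normal with mean 89.5 and SD ≈ 7.5
  mg/dl, fasting insulin with mean 13.6 and SD ≈ 9.4 µIU/ml, both loaded
  on a standard-normal insulin-resistance latent (loadings 0.4 and 0.6);
  post-load excursions scale multiplicatively with exp(0.3–0.35·latent),
  so with noise off every curve value is strictly monotone in the latent
  and ISI strictly decreasing — giving the interaction surfaces a known
  generative direction. A saturating protective carotenoid effect
  (γ·tanh of the z-scored concentration) can be subtracted from the
  latent for chosen carotenoids to generate the differential-interaction
  scenario (the demo config applies γ = 0.35 to α- and β-carotene only).

What the generator does **not** emulate — and hence what passing recovery
tests do not establish about real data: no shared-household or dominance
variance (the model fitted is the model generated, genetic + residual
only), no missingness by default, no assortative mating or age structure
within founders, no measurement batch effects, no genotype data, and
dietary intake only as an optional noisy correlate. Recovery results
therefore demonstrate correctness of the estimators under their own
assumptions, not robustness to their violation.

## Problem sizes and reproducibility

The test suite runs null-calibration checks at a reduced scale (100
families, 500 replicates) and recovery checks at full study scale
(401 families, 20 replicates), sizes chosen to give binomial/Monte-Carlo
error small enough for the stated tolerances while keeping the suite in a
few minutes. `scripts/acceptance.py` uses 200 study-scale replicates per
recovery target so that the reported means carry a Monte-Carlo SE of
≈0.005–0.01, well below the recovery tolerances; all of its randomness
derives from the single `--seed` argument. Pipeline outputs are plain
delimited text with a JSON manifest (config hash, seed, library versions)
for audit.

## Numerical details

- Eigenvalues of 2Φ blocks are clipped at 0 (they are PSD up to roundoff);
  profile evaluations return −∞ if any rotated variance falls below 1e-12.
- Univariate optimizer: grid step 0.01 + Brent refinement; convergence
  xatol 1e-8. Bivariate: L-BFGS-B, ftol 1e-12, gtol 1e-8, max 500
  iterations; log-variances bounded at ±16, Fisher-z at ±7.
- Ties in the inverse-normal transform get average ranks; an all-constant
  vector is an error (ranks undefined), as are fewer than 3 values.
- `lrt_correlation` clamps negative Λ to 0 with a warning rather than
  erroring: a constrained refit can exceed the full fit by optimizer
  tolerance.
- Gene-dropping and dense-grid likelihood oracles live in the test suite,
  deliberately independent of the implementation paths they validate.

## Known limitations

- Heritability estimates near the [0, 1] boundary are biased toward the
  interior mean of the truncated sampling distribution (see the univariate
  section); users comparing replicate SDs with reported SEs near h² = 1
  should expect the truncation gap.
- ρ_G is weakly identified when either trait's genetic variance is small;
  boundary flags should be checked before interpreting extreme genetic
  correlations from modest cohorts.
- The two-component model (genetic + residual) cannot separate shared
  environment from additive genetics; with sibling-heavy designs this
  inflates h² on real data where households matter.
- Wald intervals on the Fisher-z scale can undercover for correlations
  pinned near ±1; truncation flags are recorded instead of switching to
  profile intervals.
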