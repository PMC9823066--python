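# Methods

## The scientific problem

Low birthweight is epidemiologically associated with higher adult
cardiometabolic risk (blood pressure, glucose, lipids, BMI). Two genetic
mechanisms can produce such a correlation without any causal effect of
birthweight itself:

* **fetal pleiotropy** — variants in the child's own genome that both lower
  birthweight and raise later risk (the Fetal Insulin Hypothesis), and
* **maternal intrauterine effects** — variants in the mother's genome that
  restrict fetal growth and, through the offspring's genome or environment,
  raise the offspring's later risk (the Barker Hypothesis, genetically
  visible as a maternal-genome covariance).

Because mother and offspring share half their genomes, GWAS of "offspring
phenotype on maternal genotype" and "own phenotype on own genotype" each
mix both signals. This package separates them with a two-stage procedure:
summary-statistics GWAS → LD score regression → a small structural
equation model (SEM) over four GWAS.

## The model

Let the observed variables be the four GWAS: own birthweight (BW),
offspring birthweight via maternal genotype (BW_M), own trait (T), and
offspring trait via maternal genotype (T_M). Latent variables are the
fetal and maternal genomes acting on each trait: F_BW, M_BW, F_T, M_T.
Biometric principles fix every loading: a genome loads 1 on the GWAS of
its own carrier's genotype and 1/2 on the GWAS run on the relative's
genotype (mother–offspring genotype correlation = 1/2):

    Lambda = [[1, 1/2, 0,   0 ],
              [1/2, 1, 0,   0 ],
              [0,   0, 1,  1/2],
              [0,   0, 1/2, 1 ]]

The free parameters are the 10 unique elements of the latent covariance
Psi: four heritabilities h²(F_BW), h²(M_BW), h²(F_T), h²(M_T) and six
covariances, of which cov(F_BW, F_T) is the fetal-pleiotropy term and
cov(M_BW, M_T) the maternal (Barker-type) term. The model-implied genetic
covariance of the four GWAS is Sigma(θ) = Λ Ψ Λᵀ. With 10 observed moments
and 10 parameters the model is just-identified: df = 0, the fit is exact,
and Ψ = Λ⁻¹ S Λ⁻ᵀ in closed form (the 2×2 biometric block inverts to
[[4/3, −2/3], [−2/3, 4/3]]). The fixed 1/2 loadings implicitly undo the
fourfold power attenuation of the proxy design; no explicit correction is
applied anywhere.

Estimation minimises (s − σ(θ))ᵀ W⁻¹ (s − σ(θ)), s = vech(S), with
W = diag(V) (DWLS, the default), full V (WLS) or a normal-theory
discrepancy (ML). Because σ(θ) is *linear* in θ here, all three give the
closed-form solution; we run the optimiser anyway (BFGS, analytic gradient
for (D)WLS, gradient ∞-norm < 1e−8) and cross-check it against the closed
form in the tests. Standard errors are sandwich estimates
(ΔᵀW⁻¹Δ)⁻¹ΔᵀW⁻¹VW⁻¹Δ(ΔᵀW⁻¹Δ)⁻¹ with constant Jacobian Δ. Genetic
correlations r = ψᵢⱼ/√(ψᵢᵢψⱼⱼ) get first-order delta-method SEs from the
parameter covariance; 95 % CIs are reported untruncated with an
out-of-bounds flag when an endpoint passes ±1, and a correlation is flagged
undefined (not dropped) when a fitted variance is non-positive. Negative
variance estimates are permitted and flagged, never constrained away,
because stage-1 point estimates can legitimately go negative.

## Stage 1: LD score regression

LD scores are ℓⱼ = Σₖ r²adj(j,k) over a SNP window, with the small-sample
adjustment r²adj = r² − (1 − r²)/(n − 2) so that unlinked SNPs contribute
≈ 0 and the self term exactly 1. Univariate regression of χ² on N ℓ/M with
a free intercept estimates h² (slope) and confounding/overlap (intercept);
weights are the product of a heteroskedasticity term 1/(2(1 + N h² ℓ/M)²)
and an overcounting term 1/ℓ, with h² updated once from a first pass
(two-step weighting). Bivariate regression of z₁z₂ on √(N₁N₂) ℓ/M
estimates genetic covariance; its free intercept absorbs sample overlap ×
phenotypic correlation, which is essential here because the own and proxy
GWAS share individuals by design. (The bivariate estimand is implemented
as the product of z statistics, the standard cross-trait form.)

All k(k+1)/2 regressions for the joint covariance matrix S run on a common
partition of the shared SNP set into `n_blocks` contiguous, position-ordered
blocks (default 200, standard practice). The delete-one-block estimates
yield jackknife pseudovalues whose empirical covariance (divided by the
block count) is V, the sampling covariance of vech(S) — including the
cross-element covariances the SEM weights and sandwich need. The
half-vectorisation order is row-wise upper triangle throughout:
(0,0), (0,1), …, (0,3), (1,1), …, (3,3). S is kept on the covariance
(heritability) scale, not the correlation scale: the 1/2 loadings only
perform the proxy-attenuation correction if the scale is preserved. V is
eigenvalue-floored (with a warning) if jackknife noise makes it
indefinite. The Z > 4 heuristic for "reliable" heritability estimates is
reported as a flag next to every h².

## GWAS and meta-analysis

Associations are ordinary least squares: the phenotype is residualised on
an intercept plus covariates (sex, age, genotyping batch), then each SNP's
allele dosage is tested by simple regression, vectorised across SNPs.
A mixed model is unnecessary because the simulated cohorts contain no
cryptic relatedness — the proxy design's mother–offspring dependence
enters through the *phenotype* model, not through sample structure — and
free LDSC intercepts absorb what overlap remains. Monomorphic SNPs are
emitted with missing effect/SE and a flag rather than dropped, so SNP sets
stay aligned. Fixed-effects meta-analysis aligns alleles to the first
study (flipping signs on A1/A2 swaps, dropping strand-ambiguous A/T and
C/G SNPs with a logged count) and combines with inverse-variance weights
(default) or sample-size-weighted z statistics.

## The synthetic cohort generator

The generator emulates a single-population family cohort in which both
GWAS designs can be run: `n_pairs` genotyped mother–offspring pairs plus an
own-phenotype cohort (by default the offspring themselves, giving the
sample overlap typical of such studies).

* **Haplotypes.** SNPs come in LD blocks (`ld_block_size`, default 20).
  Within a block a latent Gaussian AR(1) with per-block correlation ρ is
  thresholded at the allele-frequency quantile (a Gaussian copula), so the
  allele-scale LD follows the bivariate-normal orthant probability — the
  tests verify this against an independent orthant-probability oracle.
  Allele frequencies are uniform on (0.05, 0.5) and per-block ρ uniform on
  (0, 0.95) by default. The ρ heterogeneity matters: it spreads LD scores
  over roughly 1–12, and LD score regression identifies the slope only
  through that spread. (With near-constant ℓ the regressor is collinear
  with the intercept and second-order biases dominate — an early design
  with a single global ρ showed exactly that failure.)
* **Transmission.** The offspring receives one maternal haplotype, chosen
  independently per LD block (free recombination between blocks, none
  within), plus one paternal haplotype. Because blocks are mutually
  independent, the transmitted paternal haplotype is distributionally a
  fresh population haplotype, so fathers are never instantiated. This
  yields an exact mother–offspring genotype correlation of 1/2 and zero
  Mendelian violations by construction.
* **Effects.** Per-SNP standardized effect rows (F_BW, M_BW, F_T, M_T) are
  iid N(0, Ψ_true/n_causal) over the causal set, so Σββᵀ ≈ Ψ_true. The
  default Ψ_true uses heritabilities 0.15/0.10/0.15/0.05 and covariances
  of a few hundredths with a negative fetal birthweight–trait term — the
  magnitudes typical of birthweight and cardiometabolic traits at
  biobank scale.
* **Phenotypes.** Offspring phenotype = own standardized dosages · fetal
  column + mother's standardized dosages · maternal column + small fixed
  covariate effects + Gaussian residual completing the unit variance
  budget (Var = ψ_FF + ψ_MM + ψ_FM + covariates + residual; the genetic
  cross term is 2·½·ψ_FM). Standardisation uses *population* frequencies
  so Ψ_true is the exact variance-scale truth.
* **LD reference.** LD scores are computed from an independently simulated
  reference panel (default 2,000 individuals) sharing the population's
  frequencies and block ρ values — the external-reference arrangement of
  real LDSC. Using the GWAS sample itself as the reference couples ℓ noise
  to χ² noise and inflates the slope.

What the generator does **not** emulate: realistic human LD maps and
recombination hotspots, imputation uncertainty, X chromosome, assortative
mating, cryptic relatedness, case-control ascertainment, and binary traits.
Passing tests therefore show that the estimator chain is correct under its
own assumptions at desk scale, not that real-data estimates would be
unbiased under those violations.

## Power of the proxy design

For a variant with standardized fetal effect √q and maternal effect √q_m,
the own-design regression slope is √q + ½√q_m and the proxy slope
√q_m + ½√q (genotype correlation ½). The 1-df association χ² has
noncentrality N R²/(1 − R²) with R² the squared slope, so for a purely
fetal effect the proxy design explains q/4 and the required-N ratio is
4(1 − q/4)/(1 − q) → 4 as q → 0. The analytic route is cross-checked by a
Monte-Carlo power simulation at a single locus with Mendelian
transmission. The choice of an infinitesimal multivariate-normal effect
model for the generator (and hence for what "q" means) is ours.

## Numerical choices and scales

* Jackknife: position-ordered contiguous blocks; estimates reported from
  the full-data fit, SEs from pseudovalue variance; the joint V shares one
  partition across all regressions so diag(V) equals the separate squared
  SEs exactly.
* Desk-scale reference experiments (documented sizes, also used by the
  test suite): full-pipeline recovery at 20,000 pairs × 20,000 SNPs × 200
  blocks over 20 seeds; LDSC calibration at 5,000 individuals × 10,000
  SNPs × 100 blocks over 10 seeds; the biometric-correlation check at
  100,000 pairs.
* LDSC needs many LD blocks to average the "realized signal" noise of a
  single effect draw: below a few thousand SNPs the χ²–ℓ relationship of
  one realisation can deviate arbitrarily from its expectation and
  block-jackknife SEs become optimistic. Tests at tiny scale therefore
  assert structural identities (attenuation ratios, intercept values)
  rather than absolute recovery; quantitative calibration claims are made
  at the scales above, where the calibration tests verify that nominal 95 %
  jackknife CIs cover the simulated truth at their stated rate.
* At the reference scale the sandwich SE of the maternal-pleiotropy
  covariance cov(M_BW, M_T) comes out around 0.025 per run. A true value
  of ±0.02 is therefore at or below one standard error, which caps the
  probability of recovering its sign well under 1 (near Φ(truth/SE) ≈ 0.8
  at best) even for an unbiased estimator — separating small
  opposite-signed maternal and fetal covariances genuinely requires
  larger samples than the reference scale, and the sign-recovery stress
  test in the acceptance suite measures exactly this limit.
* Degenerate inputs: monomorphic SNPs are masked from LD scores and
  flagged in GWAS; merges below 200 SNPs, fewer than 20 jackknife blocks,
  non-PSD Ψ_true (reported with its offending eigenvalue), and variance
  budgets above 1 all fail loudly rather than degrade silently.

## Design choices that were genuinely open

* **Estimator default DWLS** with sandwich SEs (the convention for
  genomic covariance-structure models); WLS and ML are available and
  agree here by just-identification.
* **No residual variances on the observed GWAS variables** — forced by
  just-identification; all sampling noise lives in V.
* **Meta-analysis weighting** defaults to inverse-variance with a
  sample-size-weighted z alternative, since either is defensible.
* **BP-medication adjustment before outlier trimming** (configurable in
  the sense that the functions compose either way); outlier trimming is
  single-pass, the simplest reading of a "remove beyond 4 SD" rule.
* **Friedewald validity bound** 4.5 mmol/L triglycerides, the formula's
  standard applicability limit.
* **One trait pair per SEM run**: birthweight is paired with one
  cardiometabolic trait at a time (four variables, ten parameters), and
  the pipeline loops over traits rather than fitting one large model.
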