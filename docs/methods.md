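# Methods

This note documents the models implemented in `migrisk`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions that matter for reproducing any
number the package prints.

## Study design being modelled

The package models a middle-aged case–control cohort genotyped on a dense
SNP array, with questionnaire lifestyle data (energy and macronutrient
intake, sodium, alcohol, coffee, exercise, smoking) and clinical
biochemistry (blood pressure, fasting glucose, HbA1c, lipids, BMI).
Myocardial infarction is the binary outcome; hypertension, type-2
diabetes, dyslipidemia and obesity are comorbidities defined by clinical
cut-offs, with "3GO" marking three or more of the four — a severe
metabolic-syndrome state. Around the cohort sit three summary-level
analyses: cross-trait genetic correlation from GWAS summary statistics,
colocalization of GWAS and eQTL signals at single loci, and projection of
GWAS-derived gene weights onto single-cell expression.

## Synthetic data generators

All generators take a frozen spec dataclass embedding a seed; identical
specs give byte-identical output.

**Genotypes** are diploid minor-allele dosages drawn per SNP from
Hardy–Weinberg proportions ((1−m)², 2m(1−m), m²) with m uniform in
`maf_range` (default 0.05–0.5), then masked missing completely at random
(default 2%). There is no LD between cohort SNPs, no population
structure, and no relatedness — deliberately, since the downstream
methods under test (QC filters, per-SNP scan, GMDR, PRS) treat SNPs
exchangeably. Consequently, passing tests say nothing about robustness to
stratification or cryptic relatedness.

**Phenotypes** come from a logistic model:
logit P(y=1) = β₀ + Σ β_j g_j + Σ γ_jk (g_j−ḡ_j)(g_k−ḡ_k) + Σ δ_c x_c.
Interaction terms use centred-dosage products to keep them nearly
orthogonal to main effects — a pure interaction then has per-SNP marginal
ORs ≈ 1, which is exactly the regime where GMDR adds value over a scan.
Biochemistry and lifestyle columns are drawn from marginals typical of a
middle-aged East Asian cohort (energy ≈ 1800 kcal/d; ≈ 70 en%
carbohydrate, 15 en% fat, 14 en% protein; high sodium ≈ 3.5 g/d; mostly
light drinking; ≈ 1 cup coffee/d; 60/20/20% never/former/current
smoking), independent of the outcome unless named in
`covariate_effects`. They are mutually independent — real biochemistry is
correlated (BMI with BP and lipids, etc.), so calibration results here do
not certify behaviour under strong covariate collinearity.

**Paired summary statistics** draw per-SNP z-score pairs from the
bivariate normal with the LD-score regression moments:
Var(z_t) = 1 + N_t h²_t ℓ_j/M, Cov = √(N₁N₂)·r_g·√(h²₁h²₂)·ℓ_j/M.
Default LD scores are 1 + Gamma(2, 1) (mean ≈ 3). The scale matters: the
estimator's χ² > 80 filter is meant to clip rare outliers, so the
generator keeps mean χ² = 1 + N h² ℓ̄/M in the 1–3 range of a real GWAS
at the default N = 50k, M = 20k, h² ≈ 0.3–0.4. A heavier LD-score tail
would push mean χ² far above 80 and turn the outlier filter into signal
truncation, which is a property of a mis-scaled simulation, not of the
estimator.

**Colocalization loci** place a causal variant (or two, or none) on a
grid of SNPs partitioned into LD blocks of `ld_block_size` (default 20)
with AR(1) correlation ρ = `ld_decay` (default 0.9). The z-vector per
trait is the causal amplitude attenuated by ρ^|i−c| within the causal
block, plus noise that is *marginally* standard normal and carries the
same AR(1) block correlation — i.e. z ~ MVN(R ζ, R), the actual sampling
distribution of GWAS z-statistics under LD. Independent per-SNP noise
would let every strong neighbour overtake the causal SNP and make shared
and distinct causal variants nearly indistinguishable at ρ = 0.9; the
correlated form preserves the H3/H4 contrast the five-hypothesis
framework relies on. H3 forces its two causal variants into different
blocks (and errors if only one block exists).

**Expression** is gamma-Poisson (negative binomial, variance μ + αμ²,
default dispersion α = 0.5 — typical scRNA-seq overdispersion) with
per-cell-type marker genes whose means are multiplied by a fold-elevation
≥ 1. Gene weights default to standard normal with optional pinned values.
No batch effects, doublets or ambient RNA are simulated.

## SNP quality control and scan

Filters and boundary semantics follow the stated inequalities exactly:
missing call rate ≥ 4% excluded; heterozygote fraction > 30% excluded;
exact Hardy–Weinberg test p < 0.05 excluded; minor-allele frequency < 1%
excluded, with MAF recomputed from non-missing calls and folded at 0.5.
Every violated criterion is recorded, not only the first. The HWE test is
the exact conditional test (sum of heterozygote-count probabilities no
more probable than observed, given the allele counts), computed by the
standard log-space recurrence; a χ² variant exists for speed. Note a
structural consequence of the printed thresholds: under HWE the expected
heterozygosity 2m(1−m) exceeds 0.30 for m > 0.18, so the per-SNP filter
at 30% removes common SNPs wholesale. The filter is applied per SNP
because it is listed among SNP exclusion criteria; array-level
genotyping-accuracy filtering (BRLMM confidence < 98%) happens upstream
of dosage data and is documented here rather than implemented.

The association scan fits outcome ~ dosage + covariates per SNP by
maximum-likelihood logistic regression, dropping samples with a missing
dosage for that SNP only. Separated or non-converged fits are flagged,
never fatal. Bonferroni significance is p < 0.05/m with m the number of
tested SNPs. Density hotspots bin SNPs with p < 1e-4 into fixed 1-based,
half-open 1-Mb windows per chromosome; a window with ≥ 50 significant
SNPs is a `hotspot`, any other emitted window `intermediate`, and
zero-count windows (the `background` tier) are not emitted.

## GMDR

Scores are residuals from the covariate-only logistic fit, so they sum to
zero and are orthogonal to the fitted covariates; GMDR therefore searches
for genotype structure in what the covariates cannot explain. Numerical
conventions, all configurable: a training cell with Σ s_i exactly 0 is
labelled high-risk; genotype cells unseen in training are labelled
low-risk in the test fold (conservative); samples missing a dosage inside
a combination are dropped for that combination only; a fold side with no
positive (or no negative) score mass contributes the chance level 0.5 to
its balanced-accuracy component. Cross-validation uses stratified folds
(default 10, consistent with a 10-fold sign test whose all-wins tail is
1/1024 ≈ 0.0010). Ties in per-fold best-combination selection break by
higher test accuracy, then lexicographic rsid order; the modal winner
across folds is reported with its CVC, per-fold TEBAs recomputed on the
same folds, and the exact sign-test p. The search is exhaustive over the
requested combination sizes, which is intended for the tens-of-SNPs
candidate sets that follow a scan, not for genome-wide input.

## PRS and epidemiological models

The PRS counts risk-allele copies: the minor allele when the SNP's OR > 1,
the major allele when OR < 1 (undefined at exactly 1, which raises). The
printed low/medium/high ranges (2–7 / 8–10 / 11–15) are treated as
open-ended cut points ≤ 7 / 8–10 / ≥ 11, since the end values reflect an
observed cohort minimum and maximum rather than the rule; a 9-SNP score
can in principle reach 0 and 18. A missing dosage contributes the
cohort-mean counted dosage rounded to the nearest integer (keeping the
score integer-valued), or drops the sample under `missing="drop"`; a
sample missing every model SNP has an undefined score.

Comorbidity assignment treats medication as an alternative criterion
(clinical threshold OR medication) because requiring both would exclude
treated-but-controlled patients; `strict_and=True` gives the literal
conjunction. Model 1 adjusts for age, sex, residence and BMI; Model 2
adds energy, alcohol, coffee and physical activity. The lifestyle
interaction dichotomizes the factor at its cut (protein 13 en%, CHO
70 en%, fat 15 en%, Na 2300 mg/d, alcohol 30 g/d by default with 20
supported since the source thresholds are reported inconsistently,
coffee 1 cup/d, exercise 150 min/wk; smoking: never vs current+former),
drops the covariate that coincides with the tested factor, reports the
six-cell stratified OR table against the low-PRS/low-factor reference,
and takes the interaction p as the Wald test of a single ordinal-PRS ×
factor product term — one degree of freedom, matching a single reported
p per factor. Wald inference is used throughout to match OR ± 95% CI
reporting. The Friedewald helper (LDL = TC − HDL − TG/5, undefined above
TG 500 mg/dL) is provided for completeness.

## LD score regression

Univariate slope of z² on N ℓ/M estimates h²; bivariate slope of z₁z₂ on
√(N₁N₂) ℓ/M estimates the genetic covariance, with a free intercept that
absorbs sample overlap. Weights are a single pass of 1/ℓ_j rather than
the reference tool's iterated heteroskedasticity weights — adequate for
the simulated moment structure and simpler to reason about; this is a
documented divergence, so absolute agreement with that tool on real data
is not claimed. Standard errors come from a delete-one block jackknife
over 200 SNP-ordered blocks (the r_g SE jackknifes the full ratio).
Munging intersects on rsid, drops MAF ≤ 0.05, χ² > 80, strand-ambiguous
(A/T, C/G) and allele-mismatched SNPs, flips z when effect alleles are
swapped, and honours an INFO ≥ 0.9 filter when an `info` column exists.
Raw r_g is reported alongside a [−1, 1]-clamped value so the definitional
bound can be enforced without hiding estimator behaviour. Liability-scale
conversion, partitioned heritability and constrained intercepts are out
of scope.

## Colocalization

Effect variances are approximated from MAF and sample size
(V = 1/(2N f(1−f)), divided by φ(1−φ) for case-control traits with case
fraction φ, default 0.5), so only z (or p), MAF and N are needed. Prior
effect SDs default to W = 0.15 (quantitative) and 0.2 (case-control),
the conventional choices; priors p1 = p2 = 1e-4, p12 = 1e-5. All
hypothesis sums run in log space; the H3 term S₁S₂ − S₁₂ uses a guarded
log-difference that floors at −∞ instead of going negative when
essentially all evidence sits on one SNP. When only p-values are
available, |z| = Φ⁻¹(1 − p/2); the ABF depends on z only through z², so
the unknown sign is immaterial. The implementation assumes at most one
causal variant per trait per locus — multi-causal (fine-mapping-aware)
colocalization is explicitly out of scope.

## Single-cell scoring

The scoring layer defaults to library-size normalization to 10,000
counts per cell followed by log1p, the standard scRNA-seq transform,
because the raw weighted sum would otherwise be dominated by sequencing
depth; raw-count scoring is available. Gene matching is exact and
case-sensitive (silent symbol munging is a reproducibility hazard);
weights may be negative and are never clipped, and min–max normalization
to [0, 10] is applied once across all cells jointly — never per type —
so cross-type comparisons remain meaningful. A constant score vector has
no scale and maps to all zeros with a warning. Scale invariance holds
exactly: multiplying all weights by a > 0 leaves normalized scores
unchanged. PCA→UMAP embedding is a seeded visual aid only; no statistic
depends on it.

## Problem sizes used in the checks

The test suite and acceptance script run at desk scale, chosen as the
smallest sizes at which each statistical claim is comfortably testable:
HWE conformity at n = 10,000 genotypes; OR recovery at n = 20,000
samples; null-scan calibration over 2,000 SNPs; GMDR oracle equivalence
exhaustively at ≤ 50 samples × ≤ 4 SNPs; r_g recovery at M = 20,000
SNPs; interaction type-I error over 500 null replicates at n = 800; the
colocalization check on a 500-SNP locus. The exact HWE sweep is
exhaustive over all genotype totals ≤ 200.

## Known limitations

No LD in the cohort generator (only in locus simulation); no population
structure, relatedness or imputation; single-causal-variant
colocalization; single-pass LDSC weights; no medication-effect modelling
beyond the comorbidity indicator rules; cell-type labels are inputs, not
inferred.
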