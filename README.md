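# migrisk

Genetic risk modelling of myocardial infarction (MI) in a case–control
cohort setting: SNP quality control and association scanning, detection of
SNP–SNP interactions by generalized multifactor dimensionality reduction
(GMDR), a risk-allele-counting polygenic risk score (PRS), logistic models
of PRS against MI and its metabolic comorbidities, PRS × lifestyle
interaction tests, cross-trait genetic correlation by LD score regression,
Bayesian colocalization of GWAS and eQTL signals, and GWAS-weighted
disease-relevance scoring of single cells. Every stage runs on synthetic
data produced by the package's own generators, so the full pipeline is
testable on a laptop with no genotype access.

**Who it is for** — biostatisticians and genetic epidemiologists who want a
transparent, tested reference implementation of this analysis stack (the
kind usually assembled from PLINK, the GMDR program, LDSC, `coloc` and
scanpy scripts) in one coherent Python package.

## The statistics at the core

* **GMDR.** A covariate-only logistic fit gives score residuals
  s_i = y_i − p̂_i. For a k-SNP combination, training samples fall into 3^k
  genotype cells; a cell is high-risk when Σ s_i ≥ 0. Balanced accuracy is
  the score-weighted mean of sensitivity and specificity, computed on
  training (TRBA) and held-out (TEBA) folds; cross-validation consistency
  (CVC) counts how often the same combination wins across a stratified
  k-fold split, and an exact one-sided sign test on the fold TEBAs gives
  P(X ≥ s | n folds, ½) — 10/10 folds above chance yields p = 1/1024 ≈ 0.0010.
* **PRS.** For each model SNP, the minor allele is counted when its odds
  ratio exceeds 1 and the major allele when OR < 1; the PRS is the integer
  sum of counted-allele copies, binned low (≤ 7) / medium (8–10) / high (≥ 11).
* **LD score regression.** E[z²_j] = 1 + N·h²·ℓ_j/M and
  E[z₁j z₂j] = intercept + √(N₁N₂)·ρ_g·ℓ_j/M; weighted regressions on the
  LD scores ℓ_j give h² and ρ_g, r_g = ρ_g/√(h²₁h²₂), with block-jackknife
  standard errors.
* **Colocalization.** Wakefield log-ABFs per SNP,
  ½·log(V/(V+W²)) + ½z²W²/(V+W²), combined over single-causal-variant
  configurations into posteriors PP0–PP4 for: no association, one trait
  only (H1/H2), distinct causal variants (H3), shared causal variant (H4).
* **Single-cell relevance.** S_c = Σ_g E_{c,g}·W_g over the genes shared
  with a GWAS-derived weight table, min–max normalized to 0–10, summarized
  per cell type.

See `docs/methods.md` for assumptions, defaults and numerical choices.

## Worked example

```python
import migrisk as mg

spec = mg.SimCohortSpec(
    n_samples=4000, n_snps=10, maf_range=(0.2, 0.5), missing_rate=0.01,
    intercept=-1.2,
    main_effects={"rs000001": 0.35, "rs000004": 0.30},
    interaction_effects={("rs000002", "rs000007"): 0.9},
    seed=7,
)
geno = mg.simulate_genotypes(spec)
cohort = mg.simulate_phenotypes(geno, spec)

kept, report = mg.snp_qc(geno, mg.QCThresholds(max_het=1.0))
stats = mg.association_scan(kept, cohort, ["age", "sex"])
res = mg.Gmdr(kept, cohort, covariates=["age", "sex"]).fit(
    k_range=[2], n_folds=10, seed=0
)
print(res.summary())
```

```
GMDR model selection
--------------------
combination : rs000002, rs000007
TRBA (mean) : 0.5628
TEBA (mean) : 0.5472
CVC         : 10/10
sign test p : 0.0107
```

GMDR finds the planted purely epistatic pair (rs000002, rs000007), which a
per-SNP scan cannot see (their marginal ORs are ≈ 1.01 and 1.09): the same
winning combination in all 10 folds, held-out balanced accuracy above
chance in most folds. Building the PRS from the model SNPs and fitting the
age/sex/residence/BMI-adjusted logistic model:

```python
model_snps = sorted(set(res.snp_combination) | {"rs000001", "rs000004"})
table = mg.assign_risk_alleles(stats, model_snps)
prof = mg.compute_prs(kept, table, cuts=(3, 5))   # 4 SNPs → range 0–8
cohort["category"] = prof["category"].to_numpy()
print(mg.fit_prs_logistic(cohort, "mi", model=1).round(3))
```

```
  term   or_  ci_low  ci_high   p
   low 1.000   1.000    1.000 NaN
medium 1.731   1.490    2.011 0.0
  high 2.560   1.591    4.120 0.0
```

Carrying a high count of risk alleles raises the odds of MI ~2.6-fold over
the low-PRS reference in this synthetic cohort — the qualitative pattern a
real risk-allele PRS shows, produced here from planted effects.

The same operations are exposed on the command line
(`migrisk simulate cohort|sumstats|locus|expression`, `migrisk qc`, `scan`,
`hotspots`, `gmdr`, `prs`, `assoc`, `interact`, `rg`, `coloc`, `scscore`);
run `migrisk --help`.

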