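"""Synthetic data generators for every stage of the pipeline.

Each generator emulates the statistical structure the downstream methods
assume rather than any particular cohort:

* diploid genotypes under Hardy–Weinberg equilibrium with a uniform MAF
  spectrum and missing calls;
* binary case–control outcomes from a logistic model with SNP main effects,
  pairwise SNP×SNP interactions on centred-dosage products, covariate terms,
  plus anthropometric/biochemical/lifestyle columns so comorbidity rules and
  gene–lifestyle models can be exercised;
* paired GWAS summary statistics whose z-scores follow the LD-score
  regression moment structure at a target genetic correlation;
* single loci with block-wise LD decay and a causal configuration drawn
  from the five colocalization hypotheses H0–H4;
* a negative-binomial cell × gene count matrix with planted marker genes
  and a gene-weight (z-score) table.

All generators are deterministic given their spec (which embeds a seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from ._containers import (
    ConfigurationError,
    GenotypeMatrix,
    InvalidSpecError,
)

__all__ = [
    "SimCohortSpec",
    "SimSumstatsSpec",
    "SimLocusSpec",
    "SimExpressionSpec",
    "DEFAULT_LIFESTYLE_SPEC",
    "simulate_genotypes",
    "simulate_phenotypes",
    "simulate_sumstats_pair",
    "simulate_coloc_locus",
    "simulate_expression",
]


# Lifestyle/biochemistry marginals for a middle-aged East Asian cohort:
# energy ~1800 kcal/d, carbohydrate-dominant macronutrient split
# (~70 en% CHO, ~15 en% fat, ~14 en% protein), high sodium, mostly light
# drinking, ~1 cup coffee/day. Values are (mean, sd) for truncated normals
# unless noted.
DEFAULT_LIFESTYLE_SPEC: dict = {
    "energy_kcal": {"dist": "normal", "mean": 1800.0, "sd": 450.0, "min": 500.0},
    "protein_en_pct": {"dist": "normal", "mean": 14.0, "sd": 3.0, "min": 4.0},
    "fat_en_pct": {"dist": "normal", "mean": 15.0, "sd": 6.0, "min": 1.0},
    "cho_en_pct": {"dist": "normal", "mean": 70.0, "sd": 8.0, "min": 30.0},
    "na_mg": {"dist": "normal", "mean": 3500.0, "sd": 1200.0, "min": 200.0},
    "alcohol_g": {"dist": "zero_exponential", "p_zero": 0.5, "mean": 20.0},
    "coffee_cups": {"dist": "poisson", "mean": 1.2},
    "exercise_min_wk": {"dist": "zero_gamma", "p_zero": 0.4, "mean": 150.0, "shape": 2.0},
    "smoking": {
        "dist": "categorical",
        "levels": ["non", "former", "current"],
        "probs": [0.6, 0.2, 0.2],
    },
}

#: Biochemistry / anthropometry marginals (mean, sd) used by
#: :func:`simulate_phenotypes`. Units: mmHg, mg/dL, %, kg/m².
_BIOCHEM_SPEC: dict[str, tuple[float, float]] = {
    "bmi": (24.0, 2.9),
    "sbp": (122.0, 15.0),
    "dbp": (76.0, 9.8),
    "glucose": (96.0, 20.0),
    "hba1c": (5.75, 0.75),
    "tc": (195.0, 37.0),
    "hdl": (53.0, 13.0),
    "tg": (120.0, 65.0),
}

_MED_PREVALENCE = {"ht_med": 0.15, "dm_med": 0.05, "lipid_med": 0.05}


@dataclass(frozen=True)
class SimCohortSpec:
    """Specification of a synthetic case–control cohort.

    ``main_effects`` maps rsid → per-allele log-odds-ratio; interaction
    effects apply to products of centred dosages (dosage minus its mean),
    which keeps them nearly orthogonal to the main effects.
    """

    n_samples: int
    n_snps: int
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.02
    intercept: float = -1.5
    main_effects: Mapping[str, float] = field(default_factory=dict)
    interaction_effects: Mapping[tuple[str, str], float] = field(default_factory=dict)
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    lifestyle_spec: Mapping[str, dict] = field(default_factory=lambda: dict(DEFAULT_LIFESTYLE_SPEC))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples <= 0 or self.n_snps <= 0:
            raise InvalidSpecError("n_samples and n_snps must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise InvalidSpecError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise InvalidSpecError("missing_rate must be a probability")


@dataclass(frozen=True)
class SimSumstatsSpec:
    """Paired summary statistics with a target genetic correlation.

    Per-SNP z-score pairs are bivariate normal with the LD-score regression
    moments: Var(z_tj) = 1 + N_t·h²_t·ℓ_j/M and
    Cov(z_1j, z_2j) = √(N₁N₂)·r_g·√(h²₁h²₂)·ℓ_j/M.
    """

    n_snps: int
    ld_scores: np.ndarray | None = None
    h2_1: float = 0.3
    h2_2: float = 0.3
    rg_true: float = 0.0
    N1: int = 50_000
    N2: int = 50_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps <= 0:
            raise InvalidSpecError("n_snps must be positive")
        if not -1.0 <= self.rg_true <= 1.0:
            raise InvalidSpecError("|rg_true| must be <= 1")
        for h2 in (self.h2_1, self.h2_2):
            if not 0.0 <= h2 <= 1.0:
                raise InvalidSpecError("heritabilities must lie in [0, 1]")
        if self.ld_scores is not None:
            ld = np.asarray(self.ld_scores, dtype=float)
            if ld.shape != (self.n_snps,):
                raise InvalidSpecError("ld_scores must have length n_snps")
            if np.any(ld < 1.0):
                raise InvalidSpecError("LD scores must be >= 1")
            object.__setattr__(self, "ld_scores", ld)


_CAUSAL_CONFIGS = ("H0", "H1", "H2", "H3", "H4")


@dataclass(frozen=True)
class SimLocusSpec:
    """One locus pair under a colocalization hypothesis.

    LD within non-overlapping blocks of ``ld_block_size`` SNPs decays as
    ``ld_decay ** |i - j|``; causal signal does not leak across blocks.
    """

    n_snps: int
    ld_block_size: int = 20
    causal_config: str = "H0"
    causal_z: float = 6.0
    ld_decay: float = 0.9
    N1: int = 10_000
    N2: int = 10_000
    maf_vector: np.ndarray | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1 or self.ld_block_size < 1:
            raise InvalidSpecError("n_snps and ld_block_size must be positive")
        if self.causal_config not in _CAUSAL_CONFIGS:
            raise InvalidSpecError(
                f"causal_config must be one of {_CAUSAL_CONFIGS}"
            )
        if not 0.0 <= self.ld_decay < 1.0:
            raise InvalidSpecError("ld_decay must lie in [0, 1)")
        n_blocks = -(-self.n_snps // self.ld_block_size)
        if self.causal_config == "H3" and n_blocks < 2:
            raise InvalidSpecError(
                "H3 needs >= 2 LD blocks so the two causal variants are distinct"
            )
        if self.maf_vector is not None:
            maf = np.asarray(self.maf_vector, dtype=float)
            if maf.shape != (self.n_snps,):
                raise InvalidSpecError("maf_vector must have length n_snps")
            if np.any((maf <= 0) | (maf >= 1)):
                raise InvalidSpecError("MAFs must lie in (0, 1)")
            object.__setattr__(self, "maf_vector", maf)


@dataclass(frozen=True)
class SimExpressionSpec:
    """Cell × gene negative-binomial counts with planted markers.

    ``marker_map`` maps cell-type label → {gene: fold_elevation}; the fold
    multiplies the baseline mean in that cell type only. ``weight_spec``
    draws per-gene weights W_g (GWAS-derived z-scores downstream); explicit
    values can be pinned via ``weight_spec["fixed"]``.
    """

    n_cells: int
    n_genes: int
    cell_types: Mapping[str, float] = field(
        default_factory=lambda: {"typeA": 0.5, "typeB": 0.5}
    )
    marker_map: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    baseline_mean: float = 0.5
    dispersion: float = 0.5
    weight_spec: Mapping[str, object] = field(
        default_factory=lambda: {"dist": "normal", "mean": 0.0, "sd": 1.0}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells <= 0 or self.n_genes <= 0:
            raise InvalidSpecError("n_cells and n_genes must be positive")
        props = np.array(list(self.cell_types.values()), dtype=float)
        if np.any(props < 0) or not np.isclose(props.sum(), 1.0):
            raise InvalidSpecError("cell-type proportions must be >= 0 and sum to 1")
        if self.baseline_mean < 0:
            raise InvalidSpecError("baseline_mean must be non-negative")
        for ct, genes in self.marker_map.items():
            if ct not in self.cell_types:
                raise ConfigurationError(f"marker cell type {ct!r} not in cell_types")
            for fold in genes.values():
                if fold < 1.0:
                    raise InvalidSpecError("marker fold-elevation must be >= 1")


# ---------------------------------------------------------------------------
# genotypes & phenotypes


def simulate_genotypes(spec: SimCohortSpec) -> GenotypeMatrix:
    """Draw HWE genotypes with per-SNP MAF uniform in ``spec.maf_range``.

    Genotypes are multinomial with proportions ((1−m)², 2m(1−m), m²), then
    masked missing at ``spec.missing_rate``. SNP metadata places SNPs every
    100 kb along chromosomes of 50 SNPs each.
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.maf_range
    maf = rng.uniform(lo, hi, size=spec.n_snps)

    u = rng.random((spec.n_samples, spec.n_snps))
    p_hom_major = (1.0 - maf) ** 2
    p_het = 2.0 * maf * (1.0 - maf)
    dos = np.where(u < p_hom_major, 0.0, np.where(u < p_hom_major + p_het, 1.0, 2.0))
    if spec.missing_rate > 0:
        miss = rng.random(dos.shape) < spec.missing_rate
        dos[miss] = np.nan

    rsids = [f"rs{j + 1:06d}" for j in range(spec.n_snps)]
    snps_per_chr = 50
    snps = pd.DataFrame(
        {
            "chr": [j // snps_per_chr + 1 for j in range(spec.n_snps)],
            "pos": [(j % snps_per_chr) * 100_000 + 1 for j in range(spec.n_snps)],
            "minor": "A",
            "major": "G",
            "maf": maf,
        },
        index=pd.Index(rsids, name="rsid"),
    )
    samples = pd.Index([f"S{i + 1:06d}" for i in range(spec.n_samples)], name="sample_id")
    return GenotypeMatrix(pd.DataFrame(dos, index=samples, columns=rsids), snps)


def _draw_column(rng: np.random.Generator, n: int, cfg: dict) -> np.ndarray:
    dist = cfg["dist"]
    if dist == "normal":
        x = rng.normal(cfg["mean"], cfg["sd"], n)
        return np.clip(x, cfg.get("min", -np.inf), cfg.get("max", np.inf))
    if dist == "zero_exponential":
        x = rng.exponential(cfg["mean"], n)
        x[rng.random(n) < cfg["p_zero"]] = 0.0
        return x
    if dist == "zero_gamma":
        shape = cfg.get("shape", 2.0)
        x = rng.gamma(shape, cfg["mean"] / shape, n)
        x[rng.random(n) < cfg["p_zero"]] = 0.0
        return x
    if dist == "poisson":
        return rng.poisson(cfg["mean"], n).astype(float)
    if dist == "categorical":
        return rng.choice(cfg["levels"], size=n, p=cfg["probs"])
    raise InvalidSpecError(f"unknown lifestyle distribution {dist!r}")


def simulate_phenotypes(geno: GenotypeMatrix, spec: SimCohortSpec) -> pd.DataFrame:
    """Generate a cohort table with a logistic case–control outcome.

    The linear predictor is ``intercept + Σ β_j·g_j + Σ γ_jk·(g_j−ḡ_j)(g_k−ḡ_k)
    + Σ δ_c·x_c``; missing dosages are mean-imputed inside the predictor
    only. Biochemistry and lifestyle columns are drawn independently of the
    outcome unless named in ``covariate_effects``.
    """
    for rsid in list(spec.main_effects) + [r for pair in spec.interaction_effects for r in pair]:
        if rsid not in geno.dosages.columns:
            raise ConfigurationError(f"effect rsid {rsid!r} not in genotype matrix")

    # phenotype stream is independent of the genotype stream so the same
    # cohort spec can be replayed against the same genotypes
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7_919]))
    n = geno.n_samples

    cohort = pd.DataFrame(index=geno.dosages.index)
    cohort["age"] = np.clip(rng.normal(58.0, 8.0, n), 45.0, 90.0)
    cohort["sex"] = rng.integers(0, 2, n)  # 0 female, 1 male
    cohort["residence"] = rng.choice(["urban", "rural"], size=n, p=[0.6, 0.4])
    for name, (mean, sd) in _BIOCHEM_SPEC.items():
        cohort[name] = np.clip(rng.normal(mean, sd, n), 0.0, None)
    for name, prev in _MED_PREVALENCE.items():
        cohort[name] = (rng.random(n) < prev).astype(int)
    for name, cfg in spec.lifestyle_spec.items():
        cohort[name] = _draw_column(rng, n, cfg)

    eta = np.full(n, spec.intercept, dtype=float)
    dos = geno.dosages
    filled = dos.fillna(dos.mean(axis=0))
    for rsid, beta in spec.main_effects.items():
        eta += beta * filled[rsid].to_numpy()
    for (r1, r2), gamma in spec.interaction_effects.items():
        c1 = filled[r1].to_numpy() - filled[r1].mean()
        c2 = filled[r2].to_numpy() - filled[r2].mean()
        eta += gamma * c1 * c2
    for name, delta in spec.covariate_effects.items():
        if name not in cohort.columns:
            raise ConfigurationError(f"covariate {name!r} not in cohort table")
        col = cohort[name]
        if not pd.api.types.is_numeric_dtype(col):
            raise ConfigurationError(f"covariate {name!r} is not numeric")
        eta += delta * (col.to_numpy(dtype=float) - float(col.mean()))

    p = 1.0 / (1.0 + np.exp(-eta))
    cohort.insert(0, "mi", (rng.random(n) < p).astype(int))
    return cohort


# ---------------------------------------------------------------------------
# paired summary statistics


def _sumstats_frame(rng, z, N, maf) -> pd.DataFrame:
    se = 1.0 / np.sqrt(2.0 * N * maf * (1.0 - maf))
    m = len(z)
    snps_per_chr = 1000
    return pd.DataFrame(
        {
            "rsid": [f"rs{j + 1:06d}" for j in range(m)],
            "chr": [j // snps_per_chr + 1 for j in range(m)],
            "pos": [(j % snps_per_chr) * 10_000 + 1 for j in range(m)],
            "a1": "A",
            "a2": "G",
            "beta": z * se,
            "se": se,
            "z": z,
            "p": 2.0 * stats.norm.sf(np.abs(z)),
            "n": N,
            "maf": maf,
        }
    )


def simulate_sumstats_pair(
    spec: SimSumstatsSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw a pair of GWAS summary-statistics tables sharing LD scores.

    Returns two DataFrames on the sumstats column contract plus a ``z``
    column; the LD scores used are attached to both frames as an
    ``ldscore`` column so downstream regression needs no extra file.
    """
    rng = np.random.default_rng(spec.seed)
    M = spec.n_snps
    if spec.ld_scores is None:
        # ℓ_j >= 1 with a right tail; the scale is chosen so mean χ² at the
        # default N, h², M matches the 1–3 range of a real GWAS, keeping the
        # χ² > 80 munging filter a genuine outlier cut
        ld = 1.0 + rng.gamma(2.0, 1.0, M)
    else:
        ld = np.asarray(spec.ld_scores, dtype=float)

    v1 = 1.0 + spec.N1 * spec.h2_1 * ld / M
    v2 = 1.0 + spec.N2 * spec.h2_2 * ld / M
    cov = (
        np.sqrt(spec.N1 * spec.N2)
        * spec.rg_true
        * np.sqrt(spec.h2_1 * spec.h2_2)
        * ld
        / M
    )
    e1 = rng.standard_normal(M)
    e2 = rng.standard_normal(M)
    z1 = np.sqrt(v1) * e1
    resid_var = np.clip(v2 - cov**2 / v1, 0.0, None)
    z2 = (cov / np.sqrt(v1)) * e1 + np.sqrt(resid_var) * e2

    maf = rng.uniform(0.05, 0.5, M)
    s1 = _sumstats_frame(rng, z1, spec.N1, maf)
    s2 = _sumstats_frame(rng, z2, spec.N2, maf)
    s1["ldscore"] = ld
    s2["ldscore"] = ld
    return s1, s2


# ---------------------------------------------------------------------------
# colocalization loci


def simulate_coloc_locus(spec: SimLocusSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a locus pair under one of the hypotheses H0–H4.

    Each trait's z-vector is the causal signal — ``causal_z`` attenuated by
    ``ld_decay**|i − c|`` for SNPs i in the causal variant's LD block —
    plus noise that is marginally standard normal and carries the same
    AR(1) block correlation (the sampling distribution of GWAS z-scores
    under LD: z ~ MVN(R·ζ, R)). H3 places the two causal variants in
    different blocks; H4 shares a single index.
    """
    rng = np.random.default_rng(spec.seed)
    m = spec.n_snps
    block = np.arange(m) // spec.ld_block_size
    n_blocks = int(block.max()) + 1

    def ld_noise() -> np.ndarray:
        # AR(1) within blocks: e_i = ρ·e_{i−1} + √(1−ρ²)·η_i
        eta = rng.standard_normal(m)
        e = np.empty(m)
        rho = spec.ld_decay
        for i in range(m):
            if i == 0 or block[i] != block[i - 1]:
                e[i] = eta[i]
            else:
                e[i] = rho * e[i - 1] + np.sqrt(1.0 - rho**2) * eta[i]
        return e

    def signal(causal_idx: int) -> np.ndarray:
        s = np.zeros(m)
        in_block = block == block[causal_idx]
        decay = spec.ld_decay ** np.abs(np.arange(m) - causal_idx)
        s[in_block] = spec.causal_z * decay[in_block]
        return s

    cfg = spec.causal_config
    sig1 = np.zeros(m)
    sig2 = np.zeros(m)
    if cfg in ("H1", "H3"):
        c1 = int(rng.integers(0, m))
        sig1 = signal(c1)
    if cfg in ("H2",):
        c2 = int(rng.integers(0, m))
        sig2 = signal(c2)
    if cfg == "H3":
        other_blocks = [b for b in range(n_blocks) if b != block[c1]]
        b2 = int(rng.choice(other_blocks))
        members = np.flatnonzero(block == b2)
        c2 = int(rng.choice(members))
        sig2 = signal(c2)
    if cfg == "H4":
        c = int(rng.integers(0, m))
        sig1 = signal(c)
        sig2 = signal(c)

    z1 = sig1 + ld_noise()
    z2 = sig2 + ld_noise()
    maf = (
        np.asarray(spec.maf_vector, dtype=float)
        if spec.maf_vector is not None
        else rng.uniform(0.05, 0.5, m)
    )
    s1 = _sumstats_frame(rng, z1, spec.N1, maf)
    s2 = _sumstats_frame(rng, z2, spec.N2, maf)
    # a single locus: put everything on one chromosome, 1 kb spacing
    for s in (s1, s2):
        s["chr"] = 1
        s["pos"] = np.arange(m) * 1000 + 1
    return s1, s2


# ---------------------------------------------------------------------------
# expression


def simulate_expression(spec: SimExpressionSpec) -> tuple[ad.AnnData, pd.DataFrame]:
    """Negative-binomial counts with cell-type marker elevation, plus weights.

    Returns an :class:`anndata.AnnData` (``obs['cell_type']`` labels, raw
    counts in ``X``) and a gene/weight DataFrame. Dispersion is the NB
    ``alpha`` (variance = μ + α·μ²).
    """
    rng = np.random.default_rng(spec.seed)
    genes = [f"G{j + 1:05d}" for j in range(spec.n_genes)]
    gene_index = {g: j for j, g in enumerate(genes)}
    for ct, markers in spec.marker_map.items():
        for g in markers:
            if g not in gene_index:
                raise ConfigurationError(f"marker gene {g!r} outside gene universe")

    types = list(spec.cell_types)
    probs = np.array([spec.cell_types[t] for t in types], dtype=float)
    labels = rng.choice(types, size=spec.n_cells, p=probs / probs.sum())

    mu = np.full((spec.n_cells, spec.n_genes), spec.baseline_mean, dtype=float)
    for ct, markers in spec.marker_map.items():
        rows = labels == ct
        for g, fold in markers.items():
            mu[rows, gene_index[g]] *= fold

    # NB via gamma-Poisson: shape r = 1/alpha, mean mu
    alpha = spec.dispersion
    if alpha > 0:
        r = 1.0 / alpha
        lam = rng.gamma(r, mu / r)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int32)

    adata = ad.AnnData(
        X=counts,
        obs=pd.DataFrame(
            {"cell_type": pd.Categorical(labels)},
            index=pd.Index([f"C{i + 1:06d}" for i in range(spec.n_cells)], name="cell_id"),
        ),
        var=pd.DataFrame(index=pd.Index(genes, name="gene")),
    )

    wspec = dict(spec.weight_spec)
    if wspec.get("dist", "normal") == "normal":
        w = rng.normal(wspec.get("mean", 0.0), wspec.get("sd", 1.0), spec.n_genes)
    else:
        raise InvalidSpecError(f"unknown weight distribution {wspec.get('dist')!r}")
    for g, val in dict(wspec.get("fixed", {})).items():
        if g not in gene_index:
            raise ConfigurationError(f"fixed-weight gene {g!r} outside gene universe")
        w[gene_index[g]] = val
    weights = pd.DataFrame({"gene": genes, "weight": w})
    return adata, weights
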