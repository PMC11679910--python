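"""SNP quality control, per-SNP association scan, and density hotspots.

QC applies the four dosage-level filters — call-rate, heterozygosity,
Hardy–Weinberg equilibrium, and minor-allele frequency — with the printed
boundary semantics (missing >= 4% excluded, heterozygosity > 30% excluded,
HWE p < 0.05 excluded, MAF < 1% excluded). Array-level genotyping-accuracy
filtering (BRLMM confidence) happens upstream of dosage data and is out of
scope here.

The scan fits an additive logistic model per SNP and applies Bonferroni
correction at 0.05/m; the hotspot summary bins significant SNPs into fixed
1-Mb windows per chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._containers import ConfigurationError, GenotypeMatrix, MigriskError

__all__ = [
    "QCThresholds",
    "QCReport",
    "hwe_exact_test",
    "hwe_chisq_test",
    "snp_qc",
    "association_scan",
    "density_hotspots",
]


@dataclass(frozen=True)
class QCThresholds:
    """Exclusion thresholds; boundary semantics follow the stated inequalities."""

    max_missing: float = 0.04  # excluded when missing rate >= this
    max_het: float = 0.30      # excluded when het fraction > this
    hwe_alpha: float = 0.05    # excluded when exact-test p < this
    min_maf: float = 0.01      # excluded when MAF < this

    def __post_init__(self) -> None:
        for v in (self.max_missing, self.max_het, self.hwe_alpha, self.min_maf):
            if not 0.0 <= v <= 1.0:
                raise ValueError("QC thresholds must lie in [0, 1]")


@dataclass
class QCReport:
    """Per-SNP keep/exclude flags with reasons, plus reason counts."""

    table: pd.DataFrame  # index rsid; columns kept(bool), reasons(str '|'-joined)
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return int(self.table["kept"].sum())

    @property
    def n_excluded(self) -> int:
        return int((~self.table["kept"]).sum())


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional test of Hardy–Weinberg equilibrium.

    Conditions on the observed allele counts and sums the probability of
    every heterozygote count whose conditional probability does not exceed
    the observed one (Wigginton-style mid-free two-sided exact test).

    Returns a p-value in (0, 1]. Monomorphic samples have a single
    attainable configuration, hence p = 1.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all-zero genotype counts: HWE test undefined")

    rare = 2 * min(n_AA, n_aa) + n_Aa  # rare-allele copies
    # attainable heterozygote counts share the parity of the rare count
    h_min = rare % 2
    h_max = min(rare, 2 * n - rare)
    if h_max < h_min:  # monomorphic
        return 1.0

    hets = np.arange(h_min, h_max + 1, 2)
    # unnormalized probabilities via the standard recurrence:
    # P(h+2)/P(h) = (rare-h)(2n-rare-h) / ((h+2)(h+1))
    h = hets[:-1].astype(float)
    ratios = (
        np.log(rare - h) + np.log(2 * n - rare - h)
        - np.log(h + 2.0) - np.log(h + 1.0)
    )
    logp = np.concatenate([[0.0], np.cumsum(ratios)])
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()

    obs = n_Aa
    p_obs = probs[(obs - h_min) // 2]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-12)].sum()))


def hwe_chisq_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """One-df chi-square HWE test (offered as a faster alternative)."""
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("all-zero genotype counts: HWE test undefined")
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    x2 = float(np.sum((obs - exp) ** 2 / exp))
    from scipy.stats import chi2

    return float(chi2.sf(x2, df=1))


def snp_qc(
    geno: GenotypeMatrix,
    thr: QCThresholds | None = None,
    hwe_method: str = "exact",
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the four SNP filters; returns the kept matrix and a report.

    MAF is recomputed from non-missing calls, and a recomputed frequency
    above 0.5 is folded (the filter concerns the *minor* allele). All
    violated criteria are recorded per SNP, not just the first.
    """
    if geno.n_snps == 0 or geno.n_samples == 0:
        raise ValueError("genotype matrix is empty")
    thr = thr or QCThresholds()
    hwe_fn = hwe_exact_test if hwe_method == "exact" else hwe_chisq_test

    miss = geno.missing_rate()
    het = geno.het_fraction()
    maf_raw = geno.observed_maf()
    maf = np.minimum(maf_raw, 1.0 - maf_raw)

    reasons: dict[str, list[str]] = {r: [] for r in geno.rsids}
    for rsid in geno.rsids:
        if miss[rsid] >= thr.max_missing:
            reasons[rsid].append("missing")
        if het[rsid] > thr.max_het:
            reasons[rsid].append("heterozygosity")
        nAA, nAa, naa = geno.genotype_counts(rsid)
        if hwe_fn(nAA, nAa, naa) < thr.hwe_alpha:
            reasons[rsid].append("hwe")
        if maf[rsid] < thr.min_maf:
            reasons[rsid].append("maf")

    kept = pd.Series({r: len(v) == 0 for r, v in reasons.items()})
    table = pd.DataFrame(
        {
            "kept": kept,
            "reasons": pd.Series({r: "|".join(v) for r, v in reasons.items()}),
            "missing_rate": miss,
            "het_fraction": het,
            "maf": maf,
        }
    )
    table.index.name = "rsid"
    counts: dict[str, int] = {}
    for v in reasons.values():
        for reason in v:
            counts[reason] = counts.get(reason, 0) + 1

    kept_ids = [r for r in geno.rsids if kept[r]]
    out = GenotypeMatrix(geno.dosages[kept_ids].copy(), geno.snps.loc[kept_ids].copy())
    out.snps["maf"] = maf.loc[kept_ids]
    return out, QCReport(table=table, counts=counts)


def association_scan(
    geno: GenotypeMatrix,
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    outcome: str = "mi",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-SNP additive logistic scan with Bonferroni flagging.

    Fits ``outcome ~ dosage + covariates`` per SNP, dropping samples with a
    missing dosage for that SNP only. Returns a summary-statistics frame
    (rsid, chr, pos, a1=minor, a2=major, beta, se, or_, p, n, maf,
    bonferroni_significant, converged). Separation or non-convergence sets
    ``converged=False`` with NaN estimates rather than raising.
    """
    covariates = covariates or []
    for c in covariates + [outcome]:
        if c not in cohort.columns:
            raise ConfigurationError(f"column {c!r} not in cohort table")
    y_all = cohort[outcome]
    if not set(y_all.dropna().unique()) <= {0, 1}:
        raise ValueError("outcome must be binary 0/1")

    cov = pd.get_dummies(cohort[covariates], drop_first=True, dtype=float) if covariates else None
    m = geno.n_snps
    thresh = alpha / m
    rows = []
    for rsid in geno.rsids:
        dose = geno.dosages[rsid]
        mask = dose.notna() & y_all.notna()
        if cov is not None:
            mask &= cov.notna().all(axis=1)
        X = pd.DataFrame({"dosage": dose[mask]})
        if cov is not None:
            X = pd.concat([X, cov[mask]], axis=1)
        X = sm.add_constant(X, has_constant="add")
        y = y_all[mask].astype(float)

        beta = se = p = np.nan
        converged = False
        if y.nunique() == 2 and dose[mask].nunique() > 1:
            try:
                with np.errstate(all="ignore"):
                    fit = sm.Logit(y, X).fit(disp=False, maxiter=100)
                if fit.mle_retvals.get("converged", False) and np.isfinite(fit.bse["dosage"]) and fit.bse["dosage"] < 100:
                    beta = float(fit.params["dosage"])
                    se = float(fit.bse["dosage"])
                    p = float(fit.pvalues["dosage"])
                    converged = True
            except Exception:  # statsmodels raises several flavours on separation
                converged = False

        meta = geno.snps.loc[rsid]
        rows.append(
            {
                "rsid": rsid,
                "chr": meta["chr"],
                "pos": meta["pos"],
                "a1": meta["minor"],
                "a2": meta["major"],
                "beta": beta,
                "se": se,
                "or_": np.exp(beta) if np.isfinite(beta) else np.nan,
                "p": p,
                "n": int(mask.sum()),
                "maf": meta["maf"],
                "bonferroni_significant": bool(np.isfinite(p) and p < thresh),
                "converged": converged,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["bonferroni_threshold"] = thresh
    return out


def density_hotspots(
    stats: pd.DataFrame,
    p_threshold: float = 1e-4,
    window: int = 1_000_000,
    hotspot_min: int = 50,
) -> pd.DataFrame:
    """Bin significant SNPs into fixed 1-Mb windows per chromosome.

    Windows are 1-based half-open ``[start, start + window)``. A window with
    at least ``hotspot_min`` significant SNPs is tiered ``hotspot``; any
    other emitted window is ``intermediate``. Zero-count windows (the
    ``background`` tier) are not emitted, so no significant SNPs yields an
    empty frame.
    """
    for c in ("chr", "pos", "p"):
        if c not in stats.columns:
            raise ConfigurationError(f"stats missing column {c!r}")
    bad = stats[stats["pos"].isna()]
    if len(bad):
        raise MigriskError(
            f"missing positions for rsids: {list(bad.get('rsid', bad.index))}"
        )
    sig = stats[stats["p"] < p_threshold]
    if sig.empty:
        return pd.DataFrame(columns=["chr", "window_start", "n_significant", "tier"])
    start = ((sig["pos"].astype(int) - 1) // window) * window + 1
    grouped = (
        sig.assign(window_start=start)
        .groupby(["chr", "window_start"])
        .size()
        .reset_index(name="n_significant")
        .sort_values(["chr", "window_start"])
        .reset_index(drop=True)
    )
    grouped["tier"] = np.where(
        grouped["n_significant"] >= hotspot_min, "hotspot", "intermediate"
    )
    return grouped
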