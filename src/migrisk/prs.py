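"""Risk-allele-counting polygenic risk score.

The PRS is an unweighted count of risk-allele copies over the SNPs of the
selected interaction model: the minor allele is counted for SNPs whose
odds ratio exceeds 1, the major allele for SNPs with OR below 1 (the rule
is undefined at OR = 1). Scores are binned into low (≤ 7), medium (8–10)
and high (≥ 11) categories; the printed 2–15 range reflects an observed
cohort minimum/maximum, so the cut points are treated as open-ended.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._containers import ConfigurationError, GenotypeMatrix, MigriskError

__all__ = [
    "assign_risk_alleles",
    "compute_prs",
    "categorize_prs",
    "PRS_CATEGORIES",
]

PRS_CATEGORIES = ("low", "medium", "high")


def assign_risk_alleles(stats: pd.DataFrame, snps: list[str]) -> pd.DataFrame:
    """Choose the counted allele per SNP from its association odds ratio.

    Returns a table (rsid, or_, counted_allele, counted_is_minor). Requires
    ``or_`` (or ``beta``) plus ``a1``/``a2`` columns in ``stats`` where
    ``a1`` is the minor allele.
    """
    st = stats.set_index("rsid") if "rsid" in stats.columns else stats
    missing = [r for r in snps if r not in st.index]
    if missing:
        raise ConfigurationError(f"SNPs without association records: {missing}")
    rows = []
    for rsid in snps:
        rec = st.loc[rsid]
        or_ = float(rec["or_"]) if "or_" in rec.index else float(np.exp(rec["beta"]))
        if not np.isfinite(or_) or or_ <= 0:
            raise MigriskError(f"{rsid}: odds ratio unavailable")
        if or_ == 1.0:
            raise MigriskError(f"{rsid}: OR = 1, counted allele undefined")
        counted_is_minor = or_ > 1.0
        rows.append(
            {
                "rsid": rsid,
                "or_": or_,
                "counted_allele": rec["a1"] if counted_is_minor else rec["a2"],
                "counted_is_minor": counted_is_minor,
            }
        )
    return pd.DataFrame(rows)


def compute_prs(
    geno: GenotypeMatrix,
    table: pd.DataFrame,
    missing: str = "mean",
    cuts: tuple[int, int] = (7, 10),
) -> pd.DataFrame:
    """Per-sample risk-allele count with category assignment.

    Counted-allele copies are the dosage itself when the minor allele is
    counted and ``2 − dosage`` otherwise. Missing dosages contribute the
    cohort-mean counted dosage rounded to the nearest integer
    (``missing="mean"``, keeps the PRS integer-valued) or drop the sample
    (``missing="drop"``). A sample missing every model SNP gets a NaN PRS
    and ``all_missing=True``.
    """
    if missing not in ("mean", "drop"):
        raise ValueError("missing must be 'mean' or 'drop'")
    rsids = list(table["rsid"])
    sub = geno.subset(rsids)
    dos = sub.dosages.to_numpy(dtype=float)
    is_minor = table["counted_is_minor"].to_numpy()
    counted = np.where(is_minor, dos, 2.0 - dos)  # NaN propagates

    nan_mask = np.isnan(counted)
    all_missing = nan_mask.all(axis=1)
    if missing == "mean":
        col_mean = np.round(np.nanmean(counted, axis=0))
        filled = np.where(nan_mask, col_mean, counted)
        prs = filled.sum(axis=1)
    else:
        prs = counted.sum(axis=1)  # any NaN → NaN
        prs[nan_mask.any(axis=1)] = np.nan
    prs[all_missing] = np.nan

    out = pd.DataFrame(index=sub.dosages.index)
    out["prs"] = prs
    out["all_missing"] = all_missing
    out["category"] = [
        categorize_prs(int(v), cuts) if np.isfinite(v) else None for v in prs
    ]
    return out


def categorize_prs(prs: int, cuts: tuple[int, int] = (7, 10)) -> str:
    """low (≤ cuts[0]) / medium (≤ cuts[1]) / high (above)."""
    if prs < 0:
        raise ValueError("PRS must be non-negative")
    low_max, med_max = cuts
    if prs <= low_max:
        return "low"
    if prs <= med_max:
        return "medium"
    return "high"
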