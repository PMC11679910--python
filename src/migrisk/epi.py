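"""Comorbidity definitions, PRS-category logistic models, and
PRS × lifestyle interaction analysis.

Comorbidities follow the clinical cut-offs used for a middle-aged Korean
cohort: hypertension (SBP ≥ 140 and DBP ≥ 90 mmHg, or antihypertensive
medication), type-2 diabetes (fasting glucose ≥ 126 mg/dL or anti-diabetic
medication), dyslipidemia (TG ≥ 200, TC ≥ 250 or HDL < 40 mg/dL, or
hypolipidemic medication) and obesity (BMI ≥ 25.0 kg/m²); "3GO" marks three
or more of the four. Medication is treated as an alternative criterion by
default (``strict_and=True`` requires criterion AND medication).

The PRS logistic models mirror the two reported covariate sets — Model 1:
age, sex, residence, BMI; Model 2 adds energy, alcohol and coffee intake
and physical activity — with the low-PRS category as reference. Lifestyle
interaction uses an ordinal PRS trend (0/1/2) crossed with the
dichotomized factor; the covariate matching the tested factor is dropped
("without corresponding variables").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._containers import ConfigurationError

__all__ = [
    "ComorbidityRules",
    "LifestyleCuts",
    "MODEL1_COVARIATES",
    "MODEL2_COVARIATES",
    "assign_comorbidity_groups",
    "fit_prs_logistic",
    "interaction_analysis",
    "friedewald_ldl",
]

MODEL1_COVARIATES = ["age", "sex", "residence", "bmi"]
MODEL2_COVARIATES = MODEL1_COVARIATES + [
    "energy_kcal",
    "alcohol_g",
    "coffee_cups",
    "exercise_min_wk",
]


@dataclass(frozen=True)
class ComorbidityRules:
    """Clinical thresholds for HT / T2DM / DL / OB and the 3GO composite."""

    sbp_cut: float = 140.0
    dbp_cut: float = 90.0
    glucose_cut: float = 126.0
    tg_cut: float = 200.0
    tc_cut: float = 250.0
    hdl_cut: float = 40.0
    bmi_cut: float = 25.0
    n_for_3go: int = 3
    strict_and: bool = False  # True: clinical criterion AND medication


@dataclass(frozen=True)
class LifestyleCuts:
    """Dichotomization cut-offs for the interaction analysis.

    The alcohol cut is reported inconsistently in the source cohort
    literature (30 vs 20 g/d); 30 is the default and both are accepted.
    Exercise likewise (150 min/wk vs 90 min/d); 150 min/wk is the default.
    """

    protein_en_pct: float = 13.0
    cho_en_pct: float = 70.0
    fat_en_pct: float = 15.0
    na_mg: float = 2300.0
    alcohol_g: float = 30.0
    coffee_cups: float = 1.0
    exercise_min_wk: float = 150.0
    energy_kcal: float = 1800.0

    def cut_for(self, factor: str) -> float:
        if factor == "smoking":
            raise ValueError("smoking is categorical; no numeric cut")
        if not hasattr(self, factor):
            raise ConfigurationError(f"no cut-off defined for factor {factor!r}")
        return float(getattr(self, factor))


_REQUIRED = {
    "HT": ["sbp", "dbp", "ht_med"],
    "T2DM": ["glucose", "dm_med"],
    "DL": ["tg", "tc", "hdl", "lipid_med"],
    "OB": ["bmi"],
}


def assign_comorbidity_groups(
    cohort: pd.DataFrame,
    rules: ComorbidityRules | None = None,
    outcome: str = "mi",
) -> pd.DataFrame:
    """Append boolean HT/T2DM/DL/OB/GO3 columns and MI+X composites.

    All boundary comparisons are inclusive on the printed side (glucose
    ≥ 126 is diabetic, BMI ≥ 25.0 is obese, HDL < 40 is dyslipidemic).
    Returns a copy; the input is untouched.
    """
    rules = rules or ComorbidityRules()
    needed = sorted({c for cols in _REQUIRED.values() for c in cols} | {outcome})
    missing = [c for c in needed if c not in cohort.columns]
    if missing:
        raise ConfigurationError(f"cohort missing required columns: {missing}")

    out = cohort.copy()
    join = np.logical_and if rules.strict_and else np.logical_or
    ht_clinical = (out["sbp"] >= rules.sbp_cut) & (out["dbp"] >= rules.dbp_cut)
    out["HT"] = join(ht_clinical, out["ht_med"].astype(bool))
    out["T2DM"] = join(out["glucose"] >= rules.glucose_cut, out["dm_med"].astype(bool))
    dl_clinical = (
        (out["tg"] >= rules.tg_cut)
        | (out["tc"] >= rules.tc_cut)
        | (out["hdl"] < rules.hdl_cut)
    )
    out["DL"] = join(dl_clinical, out["lipid_med"].astype(bool))
    out["OB"] = out["bmi"] >= rules.bmi_cut
    out["GO3"] = (
        out[["HT", "T2DM", "DL", "OB"]].sum(axis=1) >= rules.n_for_3go
    )
    mi = out[outcome].astype(bool)
    for name in ["HT", "T2DM", "DL", "OB", "GO3"]:
        out[f"mi_{name.lower()}"] = (mi & out[name]).astype(int)
    return out


def _design(
    cohort: pd.DataFrame, covariates: list[str]
) -> pd.DataFrame:
    """Numeric design block for covariates, dummy-coding any categoricals."""
    if not covariates:
        return pd.DataFrame(index=cohort.index)
    missing = [c for c in covariates if c not in cohort.columns]
    if missing:
        raise ConfigurationError(f"cohort missing covariates: {missing}")
    return pd.get_dummies(cohort[covariates], drop_first=True, dtype=float)


def _or_row(fit, term: str, label: str, model_tag) -> dict:
    ci = fit.conf_int().loc[term]
    return {
        "term": label,
        "or_": float(np.exp(fit.params[term])),
        "ci_low": float(np.exp(ci[0])),
        "ci_high": float(np.exp(ci[1])),
        "p": float(fit.pvalues[term]),
        "model": model_tag,
    }


def fit_prs_logistic(
    cohort: pd.DataFrame,
    outcome: str,
    prs_category: str = "category",
    covariates: list[str] | None = None,
    model: int | None = 1,
) -> pd.DataFrame:
    """Logistic regression of an outcome on PRS category (low = reference).

    ``model`` selects the standard covariate sets (1 or 2); an explicit
    ``covariates`` list overrides it (use ``model=None, covariates=[]`` for
    a crude fit). Returns an OR table with Wald 95% CIs; the reference row
    carries OR = 1 by construction. Quasi-separated fits are flagged via a
    ``converged`` column.
    """
    if covariates is None:
        if model == 1:
            covariates = MODEL1_COVARIATES
        elif model == 2:
            covariates = MODEL2_COVARIATES
        elif model is None:
            covariates = []
        else:
            raise ValueError("model must be 1, 2 or None")
    if outcome not in cohort.columns or prs_category not in cohort.columns:
        raise ConfigurationError(f"missing column {outcome!r} or {prs_category!r}")

    cat = pd.Categorical(cohort[prs_category], categories=["low", "medium", "high"])
    if (cat == "low").sum() == 0:
        raise ValueError("empty low-PRS reference stratum")
    dummies = pd.get_dummies(cat, dtype=float).drop(columns="low")
    dummies.index = cohort.index
    dummies = dummies.loc[:, dummies.sum() > 0]
    X = pd.concat([dummies, _design(cohort, covariates)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    y = cohort[outcome].astype(float)
    mask = y.notna() & X.notna().all(axis=1)
    fit = sm.Logit(y[mask], X[mask]).fit(disp=False, maxiter=200)
    converged = bool(
        fit.mle_retvals.get("converged", True) and np.isfinite(fit.bse).all()
    )

    rows = [
        {"term": "low", "or_": 1.0, "ci_low": 1.0, "ci_high": 1.0, "p": np.nan,
         "model": model}
    ]
    for cat_name in ("medium", "high"):
        if cat_name in X.columns:
            rows.append(_or_row(fit, cat_name, cat_name, model))
    out = pd.DataFrame(rows)
    out["converged"] = converged
    out.attrs["fit"] = fit
    return out


def _dichotomize(cohort: pd.DataFrame, factor: str, cut: float) -> pd.Series:
    if factor == "smoking":
        high = cohort["smoking"].isin(["current", "former"])
    else:
        high = cohort[factor] > cut
    if high.nunique() < 2:
        raise ValueError(f"factor {factor!r} is constant after dichotomization")
    return high.astype(float)


def interaction_analysis(
    cohort: pd.DataFrame,
    outcome: str,
    factor: str,
    prs_category: str = "category",
    cuts: LifestyleCuts | None = None,
    cut: float | None = None,
    covariates: list[str] | None = None,
) -> tuple[pd.DataFrame, float]:
    """PRS × lifestyle-factor interaction with stratified OR table.

    The factor is split low/high at its cut (smoking: non vs current +
    former). A single logistic model with the six PRS × factor cells
    (reference: low-PRS & low-factor) yields the stratified OR table; the
    interaction p comes from a second model with an ordinal PRS trend
    (0/1/2), the factor indicator, their product, and the covariates —
    the Wald p of the product term. The covariate equal to ``factor`` is
    dropped from the adjustment set.
    """
    if factor != "smoking" and factor not in cohort.columns:
        raise ConfigurationError(f"factor {factor!r} not in cohort table")
    cuts = cuts or LifestyleCuts()
    if cut is None and factor != "smoking":
        cut = cuts.cut_for(factor)
    covariates = MODEL2_COVARIATES if covariates is None else covariates
    covariates = [c for c in covariates if c != factor]

    high = _dichotomize(cohort, factor, cut if cut is not None else np.nan)
    cat = pd.Categorical(cohort[prs_category], categories=["low", "medium", "high"])
    trend = pd.Series(cat.codes.astype(float), index=cohort.index)
    if (trend < 0).any():
        raise ValueError("unrecognized PRS category labels")
    y = cohort[outcome].astype(float)
    covs = _design(cohort, covariates)

    # six-cell stratified model
    cells = pd.DataFrame(index=cohort.index)
    for f_level, f_name in ((0.0, "low"), (1.0, "high")):
        for p_name in ("low", "medium", "high"):
            if f_level == 0.0 and p_name == "low":
                continue  # reference cell
            cells[f"{f_name}_factor:{p_name}_prs"] = (
                (high == f_level) & (np.asarray(cat) == p_name)
            ).astype(float)
    Xs = sm.add_constant(pd.concat([cells, covs], axis=1), has_constant="add")
    mask = y.notna() & Xs.notna().all(axis=1)
    fit_s = sm.Logit(y[mask], Xs[mask]).fit(disp=False, maxiter=200)
    rows = [
        {"term": "low_factor:low_prs", "or_": 1.0, "ci_low": 1.0, "ci_high": 1.0,
         "p": np.nan, "model": 2}
    ]
    rows += [_or_row(fit_s, c, c, 2) for c in cells.columns]
    table = pd.DataFrame(rows)
    table.insert(0, "factor", factor)

    # single-df interaction test: ordinal trend × factor
    Xi = pd.DataFrame(
        {"prs_trend": trend, "factor_high": high, "prs_x_factor": trend * high}
    )
    Xi = sm.add_constant(pd.concat([Xi, covs], axis=1), has_constant="add")
    mask_i = y.notna() & Xi.notna().all(axis=1)
    fit_i = sm.Logit(y[mask_i], Xi[mask_i]).fit(disp=False, maxiter=200)
    interaction_p = float(fit_i.pvalues["prs_x_factor"])
    return table, interaction_p


def friedewald_ldl(tc, hdl, tg):
    """LDL cholesterol (mg/dL) by the Friedewald equation, TC − HDL − TG/5.

    Undefined (NaN) when TG exceeds 500 mg/dL, where the TG/5 VLDL
    approximation breaks down. Accepts scalars or arrays; negative inputs
    raise.
    """
    tc = np.asarray(tc, dtype=float)
    hdl = np.asarray(hdl, dtype=float)
    tg = np.asarray(tg, dtype=float)
    if (tc < 0).any() or (hdl < 0).any() or (tg < 0).any():
        raise ValueError("lipid concentrations must be non-negative")
    ldl = tc - hdl - tg / 5.0
    ldl = np.where(tg > 500.0, np.nan, ldl)
    return float(ldl) if ldl.ndim == 0 else ldl
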