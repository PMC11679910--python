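"""Generalized multifactor dimensionality reduction (GMDR).

GMDR detects multi-SNP (epistatic) effects on a binary outcome while
adjusting for covariates. A covariate-only logistic model yields per-sample
score residuals s_i = y_i − p̂_i; each candidate SNP combination partitions
training samples into 3^k genotype cells, each cell is labelled high-risk
when its summed score is non-negative, and the combination is graded by
balanced accuracy — the mean of the score-weighted sensitivity and
specificity — on training (TRBA) and held-out (TEBA) data. Across a
stratified k-fold split, cross-validation consistency (CVC) counts how
often the modal combination wins, and a one-sided exact sign test on the
fold TEBAs gives a significance level (10/10 folds above chance gives
p = 1/1024 ≈ 0.0010).

The model/results pair :class:`Gmdr` / :class:`GmdrResults` wraps the
functional operations for the common fit-and-summarise workflow.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import binom
from sklearn.model_selection import StratifiedKFold

from ._containers import ConfigurationError, GenotypeMatrix

__all__ = [
    "compute_scores",
    "evaluate_combination",
    "select_best_model",
    "sign_test",
    "Gmdr",
    "GmdrResults",
]


def compute_scores(
    cohort: pd.DataFrame,
    covariates: list[str] | None = None,
    outcome: str = "mi",
) -> pd.Series:
    """Score residuals y − p̂ from a covariate-only logistic fit.

    With an intercept in the null model the residuals sum to zero (the
    logistic normal equations), and are numerically orthogonal to every
    covariate in the fit.
    """
    covariates = covariates or []
    for c in covariates + [outcome]:
        if c not in cohort.columns:
            raise ConfigurationError(f"column {c!r} not in cohort table")
    y = cohort[outcome].astype(float)
    if not set(y.dropna().unique()) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if covariates:
        X = pd.get_dummies(cohort[covariates], drop_first=True, dtype=float)
        X = sm.add_constant(X, has_constant="add")
    else:
        X = pd.DataFrame({"const": np.ones(len(y))}, index=cohort.index)
    fit = sm.Logit(y, X).fit(disp=False)
    if not fit.mle_retvals.get("converged", True):
        raise RuntimeError("covariate-only logistic fit did not converge")
    scores = y - fit.predict(X)
    scores.name = "score"
    return scores


def _cell_index(dosages: np.ndarray) -> np.ndarray:
    """Map k dosage columns to a base-3 genotype cell id; NaN rows → −1."""
    ok = ~np.isnan(dosages).any(axis=1)
    cells = np.full(dosages.shape[0], -1, dtype=np.int64)
    if ok.any():
        d = dosages[ok].astype(np.int64)
        cells[ok] = d @ (3 ** np.arange(d.shape[1], dtype=np.int64))
    return cells


def _balanced_accuracy(scores: np.ndarray, cells: np.ndarray, high_risk: np.ndarray) -> float:
    """Score-weighted balanced accuracy given frozen high-risk cell labels.

    A degenerate side (no positive or no negative score mass) contributes
    the chance level 0.5 for that component.
    """
    ok = cells >= 0
    s = scores[ok]
    in_high = high_risk[cells[ok]]
    pos = s > 0
    neg = s < 0
    pos_total = s[pos].sum()
    neg_total = -s[neg].sum()
    sens = (s[pos & in_high].sum() / pos_total) if pos_total > 0 else 0.5
    spec = (-s[neg & ~in_high].sum() / neg_total) if neg_total > 0 else 0.5
    return 0.5 * (sens + spec)


def evaluate_combination(
    scores: pd.Series | np.ndarray,
    geno: GenotypeMatrix,
    combo: tuple[str, ...],
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    tie_high_risk: bool = True,
    unseen_high_risk: bool = False,
) -> tuple[float, float]:
    """TRBA and TEBA of one SNP combination for a given train/test split.

    Cell labels are learned on training samples only (a cell is high-risk
    when its summed training score is positive, with Σ = 0 ties resolved by
    ``tie_high_risk``) and frozen when scoring the test fold; cells unseen
    during training are labelled by ``unseen_high_risk`` (default:
    low-risk). Samples with a missing dosage inside ``combo`` are dropped
    for this combination only.
    """
    for r in combo:
        if r not in geno.dosages.columns:
            raise ConfigurationError(f"combo rsid {r!r} not genotyped")
    train_idx = np.asarray(train_idx)
    test_idx = np.asarray(test_idx)
    if len(train_idx) == 0:
        raise ValueError("empty training set")
    if np.intersect1d(train_idx, test_idx).size:
        raise ValueError("train and test indices overlap")

    s = np.asarray(scores, dtype=float)
    dos = geno.dosages[list(combo)].to_numpy(dtype=float)
    cells = _cell_index(dos)
    n_cells = 3 ** len(combo)

    tr_cells = cells[train_idx]
    tr_ok = tr_cells >= 0
    sums = np.bincount(tr_cells[tr_ok], weights=s[train_idx][tr_ok], minlength=n_cells)
    seen = np.bincount(tr_cells[tr_ok], minlength=n_cells) > 0
    high = np.where(sums > 0, True, np.where(sums < 0, False, tie_high_risk))
    high = np.where(seen, high, unseen_high_risk)

    trba = _balanced_accuracy(s[train_idx], tr_cells, high)
    teba = _balanced_accuracy(s[test_idx], cells[test_idx], high)
    return float(trba), float(teba)


def sign_test(teba_folds, null: float = 0.5) -> float:
    """One-sided exact binomial sign test on fold test accuracies.

    Success = fold TEBA strictly above ``null``; returns
    P(X ≥ observed | n folds, p = ½).
    """
    teba = np.asarray(teba_folds, dtype=float)
    if teba.size == 0:
        raise ValueError("empty TEBA vector")
    successes = int((teba > null).sum())
    return float(binom.sf(successes - 1, teba.size, 0.5))


@dataclass
class GmdrResults:
    """Selected GMDR model: combination, accuracies, consistency, sign test."""

    snp_combination: tuple[str, ...]
    trba: float                 # mean training balanced accuracy across folds
    teba_folds: np.ndarray      # per-fold test balanced accuracy
    cvc: int                    # folds in which this combination won
    n_folds: int
    sign_p: float
    fold_winners: list[tuple[str, ...]]

    @property
    def teba(self) -> float:
        return float(np.mean(self.teba_folds))

    def summary(self) -> str:
        lines = [
            "GMDR model selection",
            "--------------------",
            f"combination : {', '.join(self.snp_combination)}",
            f"TRBA (mean) : {self.trba:.4f}",
            f"TEBA (mean) : {self.teba:.4f}",
            f"CVC         : {self.cvc}/{self.n_folds}",
            f"sign test p : {self.sign_p:.4f}",
        ]
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rec = {
            "combination": "|".join(self.snp_combination),
            "trba": self.trba,
            "teba_mean": self.teba,
            "cvc": self.cvc,
            "n_folds": self.n_folds,
            "sign_p": self.sign_p,
        }
        for i, t in enumerate(self.teba_folds, 1):
            rec[f"teba_fold{i}"] = t
        return pd.DataFrame([rec])


def select_best_model(
    scores: pd.Series | np.ndarray,
    geno: GenotypeMatrix,
    outcome: np.ndarray | pd.Series,
    k_range=(1, 2),
    n_folds: int = 10,
    seed: int = 0,
    tie_high_risk: bool = True,
) -> GmdrResults:
    """Exhaustive k-way search with stratified cross-validation.

    Per fold, every combination of each size in ``k_range`` is scored by
    TRBA and the best one recorded (ties broken by higher TEBA, then
    lexicographic rsid order). The reported model is the modal per-fold
    winner; its CVC is the winner's frequency, and mean TRBA / per-fold
    TEBA / the sign test are recomputed for that combination on the same
    folds.
    """
    y = np.asarray(outcome)
    s = np.asarray(scores, dtype=float)
    rsids = geno.rsids
    ks = [k_range] if np.isscalar(k_range) else list(k_range)
    for k in ks:
        if k > len(rsids):
            raise ValueError(f"k={k} exceeds available SNPs ({len(rsids)})")
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < n_folds:
        raise ValueError("need at least n_folds samples in each outcome class")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(np.zeros(len(y)), y))
    combos = [c for k in ks for c in itertools.combinations(rsids, k)]

    winners: list[tuple[str, ...]] = []
    for train_idx, test_idx in splits:
        best = None  # (-trba, -teba, combo)
        for combo in combos:
            trba, teba = evaluate_combination(
                s, geno, combo, train_idx, test_idx, tie_high_risk=tie_high_risk
            )
            key = (-trba, -teba, combo)
            if best is None or key < best:
                best = key
        winners.append(best[2])

    modal = min(set(winners), key=lambda c: (-winners.count(c), c))
    cvc = winners.count(modal)
    trbas, tebas = zip(
        *(
            evaluate_combination(s, geno, modal, tr, te, tie_high_risk=tie_high_risk)
            for tr, te in splits
        )
    )
    teba_folds = np.array(tebas)
    return GmdrResults(
        snp_combination=modal,
        trba=float(np.mean(trbas)),
        teba_folds=teba_folds,
        cvc=cvc,
        n_folds=n_folds,
        sign_p=sign_test(teba_folds),
        fold_winners=winners,
    )


class Gmdr:
    """GMDR model: genotypes + binary outcome + adjustment covariates.

    Examples
    --------
    >>> model = Gmdr(geno, cohort, covariates=["age", "sex"])  # doctest: +SKIP
    >>> res = model.fit(k_range=(1, 2), n_folds=10, seed=0)    # doctest: +SKIP
    >>> print(res.summary())                                    # doctest: +SKIP
    """

    def __init__(
        self,
        geno: GenotypeMatrix,
        cohort: pd.DataFrame,
        covariates: list[str] | None = None,
        outcome: str = "mi",
    ) -> None:
        if len(cohort) != geno.n_samples:
            raise ConfigurationError("cohort and genotype matrix differ in length")
        self.geno = geno
        self.cohort = cohort
        self.covariates = covariates or []
        self.outcome = outcome
        self.scores = compute_scores(cohort, self.covariates, outcome)

    def fit(self, k_range=(1, 2), n_folds: int = 10, seed: int = 0) -> GmdrResults:
        return select_best_model(
            self.scores,
            self.geno,
            self.cohort[self.outcome].to_numpy(),
            k_range=k_range,
            n_folds=n_folds,
            seed=seed,
        )
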