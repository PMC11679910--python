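"""Bayesian colocalization with per-SNP approximate Bayes factors.

Under a single-causal-variant assumption per trait, each SNP's evidence of
association is the Wakefield approximate Bayes factor computed from its
z-score, an effect-variance approximation V built from MAF and sample size
(quantitative traits: V = 1/(2·N·f(1−f)); case-control: V divided further
by φ(1−φ) for case fraction φ), and a prior effect SD W:

    log ABF = ½·log(V/(V + W²)) + ½·z²·W²/(V + W²)

The five locus-level hypotheses — no association (H0), trait 1 only (H1),
trait 2 only (H2), both traits with distinct causal variants (H3), both
with a shared causal variant (H4) — get posterior probabilities
proportional to {1, p1·S1, p2·S2, p1·p2·(S1·S2 − S12), p12·S12}, where S1
and S2 sum each trait's ABFs over SNPs and S12 sums the products at the
same SNP. All sums run in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import norm

from ._containers import MigriskError

__all__ = [
    "ColocPriors",
    "ColocPosterior",
    "LocusPair",
    "snp_log_abf",
    "colocalize",
]

#: Default prior effect SDs on the z-appropriate scale, per trait type.
DEFAULT_PRIOR_SD = {"quant": 0.15, "cc": 0.2}


@dataclass(frozen=True)
class ColocPriors:
    """Per-SNP prior probabilities of association.

    p1/p2: causal for trait 1/2 only; p12: causal for both. Defaults are
    the conventional 1e-4, 1e-4, 1e-5.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("require 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("priors must sum to < 1")


@dataclass
class LocusPair:
    """Two aligned per-SNP vectors for one locus.

    Each trait carries z (or |z| recovered from p), MAF, N, a trait type in
    {"quant", "cc"} and, for case-control traits, the case fraction φ.
    """

    z1: np.ndarray
    z2: np.ndarray
    maf1: np.ndarray
    maf2: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    type1: str = "quant"
    type2: str = "quant"
    case_frac1: float = 0.5
    case_frac2: float = 0.5

    def __post_init__(self) -> None:
        arrays = [np.asarray(a, dtype=float) for a in
                  (self.z1, self.z2, self.maf1, self.maf2, self.n1, self.n2)]
        lengths = {a.shape for a in arrays}
        if len(lengths) != 1:
            raise MigriskError("locus vectors are misaligned")
        self.z1, self.z2, self.maf1, self.maf2, self.n1, self.n2 = arrays

    @classmethod
    def from_sumstats(
        cls,
        s1: pd.DataFrame,
        s2: pd.DataFrame,
        type1: str = "quant",
        type2: str = "quant",
        case_frac1: float = 0.5,
        case_frac2: float = 0.5,
    ) -> "LocusPair":
        """Build from two sumstats frames aligned on rsid.

        Uses a ``z`` column if present, otherwise beta/se, otherwise
        |z| = Φ⁻¹(1 − p/2) from the p-value (the ABF depends on z only
        through z², so the unknown sign is immaterial).
        """
        a = s1.set_index("rsid")
        b = s2.set_index("rsid")
        common = a.index.intersection(b.index)
        if len(common) < 2:
            raise MigriskError("need at least 2 shared SNPs at the locus")
        a, b = a.loc[common], b.loc[common]

        def z_of(df):
            if "z" in df.columns:
                return df["z"].to_numpy(dtype=float)
            if {"beta", "se"} <= set(df.columns):
                return (df["beta"] / df["se"]).to_numpy(dtype=float)
            return norm.isf(df["p"].to_numpy(dtype=float) / 2.0)

        return cls(
            z1=z_of(a), z2=z_of(b),
            maf1=a["maf"].to_numpy(dtype=float), maf2=b["maf"].to_numpy(dtype=float),
            n1=a["n"].to_numpy(dtype=float), n2=b["n"].to_numpy(dtype=float),
            type1=type1, type2=type2,
            case_frac1=case_frac1, case_frac2=case_frac2,
        )


def snp_log_abf(z, maf, n, trait_type: str = "quant", prior_sd: float | None = None,
                case_frac: float = 0.5):
    """Wakefield log approximate Bayes factor for one SNP (vectorized).

    ``prior_sd`` defaults to 0.15 for quantitative and 0.2 for
    case-control traits.
    """
    z = np.asarray(z, dtype=float)
    maf = np.asarray(maf, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any((maf <= 0) | (maf >= 1)):
        raise ValueError("MAF must lie strictly in (0, 1)")
    if np.any(n <= 0):
        raise ValueError("sample size must be positive")
    if trait_type not in DEFAULT_PRIOR_SD:
        raise ValueError("trait_type must be 'quant' or 'cc'")
    W = DEFAULT_PRIOR_SD[trait_type] if prior_sd is None else prior_sd

    V = 1.0 / (2.0 * n * maf * (1.0 - maf))
    if trait_type == "cc":
        V = V / (case_frac * (1.0 - case_frac))
    r = W**2 / (V + W**2)
    labf = 0.5 * np.log(V / (V + W**2)) + 0.5 * z**2 * r
    return labf if labf.ndim else float(labf)


def _log_diff_exp(a: float, b: float) -> float:
    """log(e^a − e^b) for a > b, −inf when the difference underflows."""
    if b >= a:
        return -np.inf
    return a + np.log1p(-np.exp(b - a))


@dataclass
class ColocPosterior:
    """PP0–PP4 plus the per-SNP log-ABFs they were built from."""

    pp: np.ndarray  # length 5, sums to 1
    labf1: np.ndarray
    labf2: np.ndarray
    n_snps: int
    priors: ColocPriors

    def __getitem__(self, h: int) -> float:
        return float(self.pp[h])

    @property
    def pp0(self): return float(self.pp[0])
    @property
    def pp1(self): return float(self.pp[1])
    @property
    def pp2(self): return float(self.pp[2])
    @property
    def pp3(self): return float(self.pp[3])
    @property
    def pp4(self): return float(self.pp[4])

    def summary(self) -> str:
        labels = [
            "H0 no association",
            "H1 trait 1 only",
            "H2 trait 2 only",
            "H3 distinct causal variants",
            "H4 shared causal variant",
        ]
        lines = ["Colocalization posteriors", "-------------------------"]
        lines += [f"PP{i} {lab:<28}: {self.pp[i]:.4f}" for i, lab in enumerate(labels)]
        lines.append(f"n SNPs: {self.n_snps}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    **{f"PP{i}": self.pp[i] for i in range(5)},
                    "n_snps": self.n_snps,
                    "p1": self.priors.p1,
                    "p2": self.priors.p2,
                    "p12": self.priors.p12,
                }
            ]
        )


def colocalize(pair: LocusPair, priors: ColocPriors | None = None,
               prior_sd1: float | None = None, prior_sd2: float | None = None) -> ColocPosterior:
    """Posterior probabilities of H0–H4 for one locus pair.

    All hypothesis sums run over single-causal-variant configurations in
    log space; the H3 term S1·S2 − S12 uses a log-difference guard so that
    near-complete overlap (all evidence at one SNP) cannot go negative.
    """
    if pair.z1.shape[0] < 2:
        raise MigriskError("need at least 2 SNPs to colocalize")
    priors = priors or ColocPriors()
    l1 = snp_log_abf(pair.z1, pair.maf1, pair.n1, pair.type1, prior_sd1, pair.case_frac1)
    l2 = snp_log_abf(pair.z2, pair.maf2, pair.n2, pair.type2, prior_sd2, pair.case_frac2)

    logS1 = float(logsumexp(l1))
    logS2 = float(logsumexp(l2))
    logS12 = float(logsumexp(l1 + l2))
    logS3 = _log_diff_exp(logS1 + logS2, logS12)

    logpost = np.array(
        [
            0.0,
            np.log(priors.p1) + logS1,
            np.log(priors.p2) + logS2,
            np.log(priors.p1) + np.log(priors.p2) + logS3,
            np.log(priors.p12) + logS12,
        ]
    )
    pp = np.exp(logpost - logsumexp(logpost))
    pp /= pp.sum()
    return ColocPosterior(pp=pp, labf1=l1, labf2=l2, n_snps=len(l1), priors=priors)
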