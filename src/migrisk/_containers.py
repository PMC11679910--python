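"""Shared data containers for the MI genetic-risk pipeline.

Genotypes are additive minor-allele dosages (0/1/2) with ``NaN`` marking a
missing call; summary statistics are plain :class:`pandas.DataFrame` objects
with a documented column contract so they can be written to / read from TSV
without a custom format.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "MigriskError",
    "InvalidSpecError",
    "ConfigurationError",
    "GenotypeMatrix",
    "SUMSTATS_COLUMNS",
    "validate_sumstats",
]


class MigriskError(Exception):
    """Base class for errors raised by this package."""


class InvalidSpecError(MigriskError, ValueError):
    """A simulation or analysis specification is internally inconsistent."""


class ConfigurationError(MigriskError, ValueError):
    """Inputs reference columns, SNPs or genes that do not exist."""


#: Column contract for per-SNP association records. ``beta`` is the additive
#: log-odds (or linear) effect of one copy of ``a1``; ``a1`` is the effect
#: (minor) allele, ``a2`` the other allele.
SUMSTATS_COLUMNS = ["rsid", "chr", "pos", "a1", "a2", "beta", "se", "p", "n", "maf"]


def validate_sumstats(df: pd.DataFrame, require: tuple[str, ...] = ("rsid",)) -> None:
    missing = [c for c in require if c not in df.columns]
    if missing:
        raise ConfigurationError(f"summary statistics missing columns: {missing}")


@dataclass
class GenotypeMatrix:
    """Samples × SNPs minor-allele dosage matrix with SNP metadata.

    Parameters
    ----------
    dosages
        DataFrame indexed by sample id, one column per rsid, values in
        {0, 1, 2} with NaN for missing calls.
    snps
        DataFrame indexed by rsid with columns ``chr``, ``pos``, ``minor``,
        ``major`` and ``maf`` (the generating or recomputed minor-allele
        frequency).
    """

    dosages: pd.DataFrame
    snps: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if not self.dosages.columns.equals(self.snps.index):
            # tolerate same set, different order
            if set(self.dosages.columns) != set(self.snps.index):
                raise ConfigurationError(
                    "dosage columns and SNP metadata index disagree"
                )
            self.snps = self.snps.loc[self.dosages.columns]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def rsids(self) -> list[str]:
        return list(self.dosages.columns)

    def subset(self, rsids) -> "GenotypeMatrix":
        rsids = list(rsids)
        missing = [r for r in rsids if r not in self.dosages.columns]
        if missing:
            raise ConfigurationError(f"unknown rsids: {missing}")
        return GenotypeMatrix(self.dosages[rsids].copy(), self.snps.loc[rsids].copy())

    def missing_rate(self) -> pd.Series:
        """Per-SNP fraction of missing calls."""
        return self.dosages.isna().mean(axis=0)

    def observed_maf(self) -> pd.Series:
        """Minor-allele frequency recomputed from non-missing calls.

        The stored minor allele stays fixed; frequencies above 0.5 are
        possible if sampling pushed the nominal minor allele past 0.5.
        """
        return self.dosages.mean(axis=0, skipna=True) / 2.0

    def het_fraction(self) -> pd.Series:
        """Per-SNP fraction of non-missing calls that are heterozygous."""
        return (self.dosages == 1).sum(axis=0) / self.dosages.notna().sum(axis=0)

    def genotype_counts(self, rsid: str) -> tuple[int, int, int]:
        """(major-hom, het, minor-hom) counts for one SNP, missing excluded."""
        col = self.dosages[rsid]
        vals = col.dropna().to_numpy()
        return int(np.sum(vals == 0)), int(np.sum(vals == 1)), int(np.sum(vals == 2))
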