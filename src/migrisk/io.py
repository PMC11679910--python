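"""Plain-text readers and writers for the pipeline's tables.

Formats: genotype TSV (samples × rsids, NA for missing) + SNP metadata
TSV; optional minimal VCF (unphased GT); cohort CSV; sumstats TSV;
LD-score TSV; per-sample PRS CSV; MTX triplet + genes.tsv/cells.tsv;
weights TSV; hotspot BED (0-based half-open).
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from ._containers import GenotypeMatrix

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_vcf",
    "write_cohort",
    "read_cohort",
    "write_sumstats",
    "read_sumstats",
    "write_ldscores",
    "read_ldscores",
    "write_weights",
    "read_weights",
    "write_expression_mtx",
    "read_expression_mtx",
    "write_hotspot_bed",
]


def write_genotypes(geno: GenotypeMatrix, prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    geno_path = prefix.with_suffix(".geno.tsv")
    snp_path = prefix.with_suffix(".snps.tsv")
    geno.dosages.to_csv(geno_path, sep="\t", na_rep="NA")
    geno.snps.to_csv(snp_path, sep="\t")
    return geno_path, snp_path


def read_genotypes(prefix: str | Path) -> GenotypeMatrix:
    prefix = Path(prefix)
    dos = pd.read_csv(prefix.with_suffix(".geno.tsv"), sep="\t", index_col=0, na_values="NA")
    snps = pd.read_csv(prefix.with_suffix(".snps.tsv"), sep="\t", index_col=0)
    return GenotypeMatrix(dos, snps)


def write_vcf(geno: GenotypeMatrix, path: str | Path) -> Path:
    """Minimal unphased VCF 4.2 with GT only. REF = major, ALT = minor, so
    the ALT count equals the stored minor-allele dosage."""
    path = Path(path)
    gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        samples = "\t".join(geno.dosages.index)
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{samples}\n")
        for rsid in geno.rsids:
            meta = geno.snps.loc[rsid]
            calls = [
                gt_map.get(v, "./.") if np.isfinite(v) else "./."
                for v in geno.dosages[rsid].to_numpy(dtype=float)
            ]
            fh.write(
                f"{meta['chr']}\t{meta['pos']}\t{rsid}\t{meta['major']}\t"
                f"{meta['minor']}\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n"
            )
    return path


def write_cohort(cohort: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    cohort.to_csv(path)
    return path


def read_cohort(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def write_sumstats(stats: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    stats.to_csv(path, sep="\t", index=False)
    return path


def read_sumstats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_ldscores(stats: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    stats[["rsid", "ldscore"]].to_csv(path, sep="\t", index=False)
    return path


def read_ldscores(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_weights(weights: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    weights[["gene", "weight"]].to_csv(path, sep="\t", index=False)
    return path


def read_weights(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_expression_mtx(adata: ad.AnnData, outdir: str | Path) -> Path:
    """MTX triplet (genes × cells, CellRanger orientation) + metadata TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(adata.X)
    sio.mmwrite(outdir / "matrix.mtx", X.T.tocoo())
    adata.var.reset_index().rename(columns={adata.var.index.name or "index": "gene"}).to_csv(
        outdir / "genes.tsv", sep="\t", index=False
    )
    obs = adata.obs.reset_index().rename(columns={adata.obs.index.name or "index": "cell_id"})
    obs.to_csv(outdir / "cells.tsv", sep="\t", index=False)
    return outdir


def read_expression_mtx(outdir: str | Path) -> ad.AnnData:
    outdir = Path(outdir)
    X = sio.mmread(outdir / "matrix.mtx").T.tocsr()
    genes = pd.read_csv(outdir / "genes.tsv", sep="\t")
    cells = pd.read_csv(outdir / "cells.tsv", sep="\t")
    return ad.AnnData(
        X=X,
        obs=cells.set_index("cell_id"),
        var=genes.set_index("gene"),
    )


def write_hotspot_bed(hotspots: pd.DataFrame, path: str | Path, window: int = 1_000_000) -> Path:
    """Hotspot windows as BED (0-based half-open, converted from 1-based)."""
    path = Path(path)
    with open(path, "w") as fh:
        for _, row in hotspots.iterrows():
            start0 = int(row["window_start"]) - 1
            fh.write(
                f"chr{row['chr']}\t{start0}\t{start0 + window}\t"
                f"{row['tier']}\t{row['n_significant']}\n"
            )
    return path
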