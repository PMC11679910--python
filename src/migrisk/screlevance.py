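"""GWAS-weighted single-cell disease-relevance scoring.

Each cell c gets a raw score S_c = Σ_{g∈G} E_{c,g}·W_g over the genes G
shared between the expression matrix and the GWAS-derived weight table,
then scores are min–max normalized to a 0–10 scale across all cells
jointly. E_{c,g} defaults to the library-size-normalized (10k counts per
cell), log1p-transformed layer; raw-count scoring is available via
``layer="counts"``. Weights are z-score-derived and may be negative; no
clipping is applied.
"""

from __future__ import annotations

import warnings

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp

from ._containers import ConfigurationError, MigriskError

__all__ = [
    "lognorm_layer",
    "intersect_genes",
    "relevance_score",
    "normalize_scores",
    "score_cells",
    "summarize_by_celltype",
    "dotplot_stats",
    "embed_cells",
]


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def lognorm_layer(adata: ad.AnnData, target_sum: float = 1e4) -> ad.AnnData:
    """Attach a ``lognorm`` layer: counts scaled to ``target_sum`` per cell,
    then log1p. Cells with zero totals stay all-zero."""
    import scanpy as sc

    if "lognorm" in adata.layers:
        return adata
    adata.layers["counts"] = adata.X.copy()
    norm = sc.pp.normalize_total(adata, target_sum=target_sum, inplace=False)["X"]
    adata.layers["lognorm"] = np.log1p(norm)
    return adata


def intersect_genes(adata: ad.AnnData, weights: pd.DataFrame) -> list[str]:
    """Exact-identifier intersection, ordered as in the expression matrix.

    Matching is case-sensitive on purpose: silent symbol munging is a
    reproducibility hazard. Drop counts are attached to the returned list
    via a ``report`` attribute-free convention — see the return tuple of
    :func:`score_cells` for the logged version.
    """
    wgenes = set(weights["gene"])
    if len(wgenes) != len(weights):
        raise MigriskError("duplicate genes in weight table")
    common = [g for g in adata.var_names if g in wgenes]
    if not common:
        raise MigriskError("no genes shared between expression and weights")
    return common


def relevance_score(
    adata: ad.AnnData,
    weights: pd.DataFrame,
    genes: list[str],
    layer: str = "lognorm",
) -> np.ndarray:
    """Raw per-cell score: dot product of expression over ``genes`` with W_g."""
    if not genes:
        raise MigriskError("empty gene set")
    if layer == "X":
        X = adata[:, genes].X
    else:
        if layer not in adata.layers and layer == "lognorm":
            lognorm_layer(adata)
        X = adata[:, genes].layers[layer]
    E = _dense(X)
    w = weights.set_index("gene").loc[genes, "weight"].to_numpy(dtype=float)
    if np.isnan(E).any() or np.isnan(w).any():
        raise ValueError("NaN in expression or weights")
    return E @ w


def normalize_scores(S: np.ndarray) -> np.ndarray:
    """Min–max scale raw scores to [0, 10].

    A constant vector has no scale; it maps to all zeros with a warning
    (the formula's denominator is zero there).
    """
    S = np.asarray(S, dtype=float)
    if S.size == 0:
        raise ValueError("empty score vector")
    lo, hi = S.min(), S.max()
    if hi == lo:
        warnings.warn("constant score vector: normalized scores set to 0", stacklevel=2)
        return np.zeros_like(S)
    return (S - lo) / (hi - lo) * 10.0


def score_cells(
    adata: ad.AnnData,
    weights: pd.DataFrame,
    layer: str = "lognorm",
    cell_type_key: str = "cell_type",
) -> pd.DataFrame:
    """End-to-end scoring: intersect, weight-sum, normalize.

    Returns a per-cell table (raw ``score``, ``score_norm`` in [0, 10],
    ``cell_type``) indexed by cell id, with intersection drop counts in
    ``attrs``.
    """
    genes = intersect_genes(adata, weights)
    raw = relevance_score(adata, weights, genes, layer=layer)
    out = pd.DataFrame(
        {
            "score": raw,
            "score_norm": normalize_scores(raw),
            "cell_type": adata.obs[cell_type_key].to_numpy(),
        },
        index=adata.obs_names,
    )
    out.attrs["n_common_genes"] = len(genes)
    out.attrs["n_dropped_expr"] = adata.n_vars - len(genes)
    out.attrs["n_dropped_weights"] = len(weights) - len(genes)
    return out


def summarize_by_celltype(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-cell-type summary of normalized scores, ranked by mean.

    Columns: cell count, mean/median, quartiles. Cells with a null type
    label are an error (listed in the message).
    """
    if scores["cell_type"].isna().any():
        bad = list(scores.index[scores["cell_type"].isna()])
        raise MigriskError(f"unlabeled cells: {bad[:20]}{'...' if len(bad) > 20 else ''}")
    g = scores.groupby("cell_type", observed=True)["score_norm"]
    out = pd.DataFrame(
        {
            "n_cells": g.size(),
            "mean": g.mean(),
            "median": g.median(),
            "q25": g.quantile(0.25),
            "q75": g.quantile(0.75),
        }
    ).sort_values("mean", ascending=False)
    out.index.name = "cell_type"
    return out


def dotplot_stats(
    adata: ad.AnnData,
    genes: list[str],
    layer: str = "lognorm",
    cell_type_key: str = "cell_type",
) -> pd.DataFrame:
    """Mean expression and fraction of expressing cells per gene × type.

    Fraction counts cells with value > 0; the mean runs over all cells of
    the type (the usual dot-plot statistics).
    """
    missing = [g for g in genes if g not in adata.var_names]
    if missing:
        raise ConfigurationError(f"genes not in expression matrix: {missing}")
    if layer == "X":
        X = adata[:, genes].X
    else:
        if layer not in adata.layers and layer == "lognorm":
            lognorm_layer(adata)
        X = adata[:, genes].layers[layer]
    E = _dense(X)
    types = adata.obs[cell_type_key]
    rows = []
    for ct in pd.unique(types):
        mask = (types == ct).to_numpy()
        sub = E[mask]
        for j, g in enumerate(genes):
            rows.append(
                {
                    "cell_type": ct,
                    "gene": g,
                    "mean_expression": float(sub[:, j].mean()),
                    "fraction_expressing": float((sub[:, j] > 0).mean()),
                }
            )
    return pd.DataFrame(rows)


def embed_cells(
    adata: ad.AnnData,
    n_comps: int = 20,
    n_neighbors: int = 15,
    seed: int = 0,
) -> pd.DataFrame:
    """PCA → UMAP 2-D embedding (a visual aid, not part of any statistic).

    Coordinates are written to ``adata.obs[['umap1', 'umap2']]`` and
    returned. Deterministic for a fixed seed.
    """
    import scanpy as sc

    if adata.n_obs <= n_comps:
        raise ValueError("fewer cells than requested components")
    work = adata.copy()
    if "lognorm" not in work.layers:
        lognorm_layer(work)
    work.X = work.layers["lognorm"]
    sc.pp.pca(work, n_comps=n_comps, random_state=seed)
    sc.pp.neighbors(work, n_neighbors=n_neighbors, random_state=seed)
    sc.tl.umap(work, random_state=seed)
    coords = pd.DataFrame(
        work.obsm["X_umap"], columns=["umap1", "umap2"], index=work.obs_names
    )
    adata.obs[["umap1", "umap2"]] = coords
    return coords
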