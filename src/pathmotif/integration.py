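"""Atlas integration: from single-cell datasets to a cell-state matrix.

A "cell state" is a cluster of single cells from one dataset, represented by
the average of its members' log-normalized transcriptomes (pseudo-bulk).
Multiple datasets are integrated by intersecting their gene sets,
concatenating their cell states, back-transforming the log averages to
"counts", and renormalizing every state to a common depth before selecting
highly variable genes and embedding with PCA.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc

log = logging.getLogger(__name__)

#: default per-cell / per-state normalization depth
TARGET_SUM = 1e4


@dataclass
class CellStateMatrix:
    """Cluster-averaged expression with per-state metadata.

    ``values`` is states × genes, non-negative, with unique gene columns.
    Depending on the pipeline stage it holds log-normalized averages
    (straight out of :func:`pseudobulk`) or renormalized linear-scale
    "counts" (out of :func:`renormalize_integrate`).
    """

    values: pd.DataFrame
    state_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate gene names in CellStateMatrix")
        if np.isnan(self.values.to_numpy()).any():
            raise ValueError("NaN in CellStateMatrix values")
        self.state_meta = self.state_meta.loc[self.values.index]

    @property
    def gene_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_states(self) -> int:
        return self.values.shape[0]


@dataclass
class EmbeddingSpace:
    """HVG/PCA embedding of cell states, row-aligned with its source matrix."""

    hvg_list: list[str]
    pc_coords: np.ndarray
    explained_variance: np.ndarray
    state_ids: pd.Index = field(default=None)

    @property
    def n_pc(self) -> int:
        return self.pc_coords.shape[1]

    def coords_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pc_coords, index=self.state_ids)


class EmptyResultError(RuntimeError):
    """Raised when a filtering step removes everything."""


def _lognormalize(adata: ad.AnnData, target_sum: float = TARGET_SUM) -> ad.AnnData:
    out = adata.copy()
    sc.pp.normalize_total(out, target_sum=target_sum)
    sc.pp.log1p(out)
    return out


def qc_filter(
    adata: ad.AnnData,
    min_counts: int = 2000,
    max_mito_frac: float = 0.2,
    min_genes: int = 200,
    mito_prefix: str = "mt-",
) -> ad.AnnData:
    """Remove low-quality cells.

    A cell is kept when its total count is at least ``min_counts`` (default
    2,000), its mitochondrial fraction (genes whose name starts with
    ``mito_prefix``, case-insensitive) is at most ``max_mito_frac``, and it
    detects at least ``min_genes`` genes. Cell order is preserved.
    """
    x = adata.X
    x = np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)
    totals = x.sum(axis=1)
    n_genes = (x > 0).sum(axis=1)
    is_mito = np.array(
        [g.lower().startswith(mito_prefix.lower()) for g in adata.var_names]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, x[:, is_mito].sum(axis=1) / totals, 1.0)
    keep = (totals >= min_counts) & (mito_frac <= max_mito_frac) & (n_genes >= min_genes)
    if not keep.any():
        raise EmptyResultError("QC removed every cell")
    return adata[keep].copy()


def cluster_dataset(
    adata: ad.AnnData,
    n_pc: int = 50,
    resolution: float = 1.0,
    seed: int = 0,
) -> np.ndarray:
    """Leiden-cluster the cells of one dataset.

    Standard route: log-normalize, PCA to ``n_pc`` components, kNN graph,
    Leiden at ``resolution``. Deterministic for a fixed seed. Returns dense
    integer labels from 0.
    """
    work = _lognormalize(adata)
    n_comps = min(n_pc, work.n_obs - 1, work.n_vars - 1)
    if n_comps < n_pc:
        warnings.warn(f"reducing n_pc from {n_pc} to {n_comps} (too few cells/genes)")
    sc.pp.pca(work, n_comps=n_comps, svd_solver="arpack", random_state=seed)
    sc.pp.neighbors(work, use_rep="X_pca", random_state=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        sc.tl.leiden(
            work,
            resolution=resolution,
            random_state=seed,
            flavor="igraph",
            n_iterations=2,
            directed=False,
        )
    return work.obs["leiden"].astype(int).to_numpy()


def pseudobulk(
    adata: ad.AnnData,
    labels: np.ndarray,
    dataset_id: str = "dataset0",
    target_sum: float = TARGET_SUM,
) -> CellStateMatrix:
    """Average log-normalized expression per cluster into one row per state.

    State metadata carries the dataset id and, where the cells provide
    ``annotation`` / ``organ`` / ``cell_class`` / ``stage`` columns, the
    majority value per cluster (ties broken lexicographically).
    """
    labels = np.asarray(labels)
    if len(labels) != adata.n_obs:
        raise ValueError("labels must cover all cells")
    logn = _lognormalize(adata, target_sum)
    x = logn.X
    x = np.asarray(x.todense()) if hasattr(x, "todense") else np.asarray(x)
    rows, meta_rows, index = [], [], []
    for lab in np.unique(labels):
        members = labels == lab
        if not members.any():
            warnings.warn(f"empty cluster {lab} skipped")
            continue
        rows.append(x[members].mean(axis=0))
        meta = {"dataset": dataset_id, "cluster": int(lab), "n_cells": int(members.sum())}
        for col in ("annotation", "organ", "cell_class", "stage", "clade",
                    "state", "profile_truth"):
            if col in adata.obs:
                counts = adata.obs.loc[members, col].astype(str).value_counts()
                top = counts[counts == counts.max()].index.sort_values()[0]
                if (counts == counts.max()).sum() > 1:
                    log.warning("tie in majority %s for cluster %s; using %r", col, lab, top)
                meta[col] = top
        meta_rows.append(meta)
        index.append(f"{dataset_id}:{lab}")
    values = pd.DataFrame(np.vstack(rows), index=index, columns=list(adata.var_names))
    return CellStateMatrix(values, pd.DataFrame(meta_rows, index=index))


def intersect_and_concat(matrices: list[CellStateMatrix]) -> CellStateMatrix:
    """Concatenate state matrices over the intersection of their gene sets.

    Genes are restricted to those detected in every matrix (sorted order);
    rows keep their dataset provenance. Raises on an empty intersection.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    genes = set(matrices[0].gene_names)
    for m in matrices[1:]:
        genes &= set(m.gene_names)
    if not genes:
        raise ValueError("empty gene intersection across datasets")
    order = sorted(genes)
    values = pd.concat([m.values[order] for m in matrices], axis=0)
    meta = pd.concat([m.state_meta for m in matrices], axis=0)
    if values.index.duplicated().any():
        values.index = meta.index = [
            f"{i}|{ix}" for i, ix in enumerate(values.index)
        ]
    return CellStateMatrix(values, meta)


def _fix_pca_signs(coords: np.ndarray, components: np.ndarray) -> np.ndarray:
    """Deterministic sign convention: largest-|loading| entry positive."""
    signs = np.sign(components[np.arange(components.shape[0]),
                               np.abs(components).argmax(axis=1)])
    signs[signs == 0] = 1.0
    return coords * signs[None, :]


def embed_states(
    m: CellStateMatrix,
    n_hvg: int = 4000,
    n_pc: int = 50,
    seed: int = 0,
) -> EmbeddingSpace:
    """HVG selection + scaled PCA on a renormalized (linear-scale) state matrix.

    Dispersion-based HVG ranking on the log1p matrix, unit-variance scaling,
    then PCA with a deterministic sign convention.
    """
    adata = ad.AnnData(
        m.values.to_numpy().astype(np.float32),
        obs=pd.DataFrame(index=m.values.index),
        var=pd.DataFrame(index=m.values.columns),
    )
    sc.pp.log1p(adata)
    n_top = min(n_hvg, adata.n_vars)
    if n_top < n_hvg:
        warnings.warn(f"only {adata.n_vars} genes available; using all as HVGs")
    if n_top < adata.n_vars:
        sc.pp.highly_variable_genes(adata, n_top_genes=n_top, flavor="seurat")
        hvgs = list(adata.var_names[adata.var["highly_variable"]])
    else:
        hvgs = list(adata.var_names)
    sub = adata[:, hvgs].copy()
    sc.pp.scale(sub)
    sub.X = np.nan_to_num(np.asarray(sub.X))  # zero-variance genes scale to 0
    n_comps = min(n_pc, sub.n_obs - 1, sub.n_vars - 1)
    if n_comps < n_pc:
        warnings.warn(f"reducing n_pc from {n_pc} to {n_comps}")
    if not np.any(sub.X):  # degenerate: identical states, zero variance
        coords = np.zeros((sub.n_obs, n_comps))
        variance = np.zeros(n_comps)
    else:
        sc.pp.pca(sub, n_comps=n_comps, svd_solver="arpack", random_state=seed)
        coords = _fix_pca_signs(
            np.asarray(sub.obsm["X_pca"], dtype=float),
            np.asarray(sub.varm["PCs"], dtype=float).T,
        )
        variance = np.asarray(sub.uns["pca"]["variance"], dtype=float)
    return EmbeddingSpace(
        hvg_list=hvgs,
        pc_coords=coords,
        explained_variance=variance,
        state_ids=m.values.index,
    )


def renormalize_integrate(
    m: CellStateMatrix,
    target_sum: float = TARGET_SUM,
    n_hvg: int = 4000,
    n_pc: int = 50,
    seed: int = 0,
    literal_exp_plus_one: bool = False,
) -> tuple[CellStateMatrix, EmbeddingSpace]:
    """Second-round normalization of the concatenated log-average matrix.

    The log-normalized averages are back-transformed to linear-scale
    "counts" with expm1 (the inverse of log1p; ``literal_exp_plus_one``
    switches to exp(x)+1 for strict reproduction of an alternative
    convention), every state is rescaled to ``target_sum`` total, and an
    HVG/PCA embedding is computed on the rescaled matrix. The returned
    matrix holds the renormalized linear-scale values; pathway scaling
    starts from it.
    """
    x = m.values.to_numpy(dtype=float)
    counts = np.exp(x) + 1.0 if literal_exp_plus_one else np.expm1(x)
    totals = counts.sum(axis=1, keepdims=True)
    if (totals == 0).any():
        raise ValueError("state with zero total expression cannot be renormalized")
    norm = counts / totals * target_sum
    out = CellStateMatrix(
        pd.DataFrame(norm, index=m.values.index, columns=m.values.columns),
        m.state_meta.copy(),
    )
    emb = embed_states(out, n_hvg=n_hvg, n_pc=n_pc, seed=seed)
    return out, emb
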