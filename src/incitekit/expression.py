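"""Normalization, embedding, clustering and differential expression.

Mirrors the standard single-nucleus workflow: per-nucleus total-count
normalization followed by ln(x+1); highly-variable-gene selection by
mean band and binned normalized dispersion; per-gene regression against
total UMI followed by unit-variance scaling with clipping; PCA (arpack),
a k-nearest-neighbour graph, Leiden community detection and a 2-D
embedding for visualization. Batch structure is handled by a pluggable
correction stage whose default is per-batch mean-centering in PC space
(model-based integration such as Harmony is an external backend, not
re-implemented here).

The two-pass strategy separates cell-type discovery from disease-state
discovery: the first pass corrects both well batch and donor so nuclei
cluster by cell type; the second pass re-clusters one cell type correcting
only the well batch, so donor/disease structure is retained.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.stats as st
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .datatypes import GeneCountMatrix


@dataclass
class HVGParams:
    """Mean band and dispersion cut-off for variable-gene selection."""

    min_mean: float = 0.0015
    max_mean: float = 0.18
    min_disp: float = 0.30
    n_bins: int = 20

    def __post_init__(self) -> None:
        if not self.min_mean < self.max_mean:
            raise ValueError("min_mean must be below max_mean")


@dataclass
class EmbeddingResult:
    """PCs, neighbour graph, cluster labels and 2-D coordinates."""

    pcs: np.ndarray
    connectivities: sp.spmatrix
    labels: np.ndarray
    umap: np.ndarray | None
    nucleus_ids: list[str]

    def label_series(self) -> pd.Series:
        return pd.Series(self.labels, index=self.nucleus_ids, name="cluster")


def normalize_log1p(
    gex: GeneCountMatrix | sp.spmatrix | np.ndarray, target_sum: float = 1e4
) -> np.ndarray:
    """Scale each nucleus to ``target_sum`` total counts, then ln(x+1)."""
    X = gex.values if isinstance(gex, GeneCountMatrix) else gex
    X = np.asarray(X.todense() if sp.issparse(X) else X, dtype=float)
    totals = X.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("nucleus with zero total counts (run QC first)")
    return np.log1p(X * (target_sum / totals)[:, None])


def select_hvg(lognorm: np.ndarray, params: HVGParams = HVGParams()) -> np.ndarray:
    """Boolean mask of highly variable genes.

    Delegates to the scanpy implementation of the binned-dispersion
    procedure (mean within the configured band, variance/mean ratio
    z-scored within ``n_bins`` mean bins above ``min_disp``).
    """
    import anndata as ad
    import scanpy as sc

    adata = ad.AnnData(np.asarray(lognorm, dtype=np.float32))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.highly_variable_genes(
            adata,
            flavor="seurat",
            min_mean=params.min_mean,
            max_mean=params.max_mean,
            min_disp=params.min_disp,
            n_bins=params.n_bins,
        )
    return adata.var["highly_variable"].to_numpy()


def regress_and_scale(
    lognorm: np.ndarray,
    covariates: np.ndarray,
    max_value: float = 10.0,
) -> np.ndarray:
    """Residualize each gene against per-nucleus covariates, then z-score.

    Ordinary least squares with an intercept; residuals are scaled to unit
    variance and clipped at ``max_value``. Genes with zero residual
    variance are left at 0.
    """
    X = np.asarray(lognorm, dtype=float)
    C = np.asarray(covariates, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    design = np.column_stack([np.ones(len(X)), C])
    beta, *_ = np.linalg.lstsq(design, X, rcond=None)
    resid = X - design @ beta
    sd = resid.std(axis=0)
    out = np.zeros_like(resid)
    # genes fit exactly by the covariates leave numerically-zero residuals;
    # scaling those would amplify rounding noise to unit variance
    nz = sd > 1e-9 * max(float(np.abs(X).max()), 1.0)
    out[:, nz] = resid[:, nz] / sd[nz]
    return np.clip(out, -max_value, max_value)


def center_by_group(pcs: np.ndarray, groups) -> np.ndarray:
    """Default batch correction: subtract each group's mean in PC space."""
    pcs = pcs.copy()
    groups = np.asarray(groups)
    for g in np.unique(groups):
        sel = groups == g
        pcs[sel] -= pcs[sel].mean(axis=0)
    return pcs


def embed_and_cluster(
    scaled: np.ndarray,
    nucleus_ids,
    n_pcs: int = 40,
    k: int = 10,
    resolution: float = 0.8,
    batch: np.ndarray | None = None,
    seed: int = 0,
    compute_umap: bool = False,
    correction=center_by_group,
) -> EmbeddingResult:
    """PCA, batch correction, kNN graph, Leiden clustering, optional UMAP.

    ``batch`` may stack several categorical covariates (a sequence of
    per-nucleus label arrays); each is centered out of PC space in turn.
    Deterministic for a fixed seed.
    """
    import anndata as ad
    import scanpy as sc

    X = np.asarray(scaled, dtype=float)
    max_pcs = min(X.shape) - 1
    if n_pcs > max_pcs:
        warnings.warn(f"n_pcs={n_pcs} clipped to {max_pcs}")
        n_pcs = max_pcs
    pca = PCA(n_components=n_pcs, svd_solver="arpack", random_state=seed)
    pcs = pca.fit_transform(X)
    if batch is not None and correction is not None:
        layers = batch if isinstance(batch, (list, tuple)) else [batch]
        for labels in layers:
            if len(np.unique(np.asarray(labels))) > 1:
                pcs = correction(pcs, labels)

    adata = ad.AnnData(
        np.zeros((len(pcs), 1), dtype=np.float32),
        obs=pd.DataFrame(index=pd.Index([str(i) for i in nucleus_ids])),
    )
    adata.obsm["X_pca"] = pcs
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sc.pp.neighbors(adata, n_neighbors=k, use_rep="X_pca", random_state=seed)
        sc.tl.leiden(
            adata,
            resolution=resolution,
            random_state=seed,
            flavor="igraph",
            n_iterations=2,
            directed=False,
        )
        umap = None
        if compute_umap:
            sc.tl.umap(adata, random_state=seed)
            umap = np.asarray(adata.obsm["X_umap"])
    return EmbeddingResult(
        pcs=pcs,
        connectivities=adata.obsp["connectivities"],
        labels=adata.obs["leiden"].to_numpy(dtype=object),
        umap=umap,
        nucleus_ids=list(nucleus_ids),
    )


def two_pass_subcluster(
    lognorm: np.ndarray,
    nucleus_ids,
    subset_mask: np.ndarray,
    total_umi: np.ndarray,
    batch: np.ndarray,
    n_pcs: int = 40,
    k: int = 10,
    resolution: float = 0.8,
    seed: int = 0,
    compute_umap: bool = False,
    min_nuclei: int = 50,
) -> EmbeddingResult:
    """Re-embed and re-cluster one cell type with batch-only correction.

    ``subset_mask`` selects the nuclei of the cell type isolated in silico
    from the first pass. Only the well batch is corrected, so donor and
    disease structure is retained in the subclusters.
    """
    subset_mask = np.asarray(subset_mask)
    if subset_mask.sum() < min_nuclei:
        raise ValueError(
            f"subset has {int(subset_mask.sum())} nuclei; need >= {min_nuclei}"
        )
    idx = np.flatnonzero(subset_mask)
    sub = regress_and_scale(
        np.asarray(lognorm)[idx], np.asarray(total_umi, dtype=float)[idx]
    )
    return embed_and_cluster(
        sub,
        [nucleus_ids[i] for i in idx],
        n_pcs=n_pcs,
        k=k,
        resolution=resolution,
        batch=np.asarray(batch)[idx],
        seed=seed,
        compute_umap=compute_umap,
    )


def differential_expression(
    lognorm_a: np.ndarray,
    lognorm_b: np.ndarray,
    gene_names,
) -> pd.DataFrame:
    """Welch two-sample t-test per gene between two nucleus groups.

    Log fold change is the difference of group means of the ln(x+1)
    expression; p-values are Benjamini-Hochberg adjusted. Genes with zero
    variance in both groups and equal means get t=0, p=1.
    """
    A = np.asarray(lognorm_a, dtype=float)
    B = np.asarray(lognorm_b, dtype=float)
    if len(A) < 2 or len(B) < 2:
        raise ValueError("each group needs at least 2 nuclei")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = st.ttest_ind(A, B, axis=0, equal_var=False)
    lfc = A.mean(axis=0) - B.mean(axis=0)
    degenerate = ~np.isfinite(t)
    t = np.where(degenerate & (lfc == 0), 0.0, t)
    p = np.where(degenerate & (lfc == 0), 1.0, p)
    # zero within-group variance but different means: infinitely confident
    with np.errstate(invalid="ignore"):
        t = np.where(~np.isfinite(t), np.sign(lfc) * np.inf, t)
    p = np.where(np.isnan(p), 0.0, p)
    q = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {"lfc": lfc, "t": t, "pval": p, "qval": q},
        index=pd.Index(gene_names, name="gene"),
    )


def cluster_proportions(meta: pd.DataFrame, labels: pd.Series) -> pd.DataFrame:
    """Per-donor fraction of nuclei in each cluster (rows sum to 1)."""
    if meta["donor_id"].nunique() < 3:
        raise ValueError("need at least 3 donors for proportion analysis")
    df = pd.DataFrame(
        {"donor_id": meta.loc[labels.index, "donor_id"], "cluster": labels}
    )
    counts = pd.crosstab(df["donor_id"], df["cluster"])
    empty = counts.sum(axis=1) == 0
    if empty.any():
        warnings.warn(f"donors with no nuclei excluded: {list(counts.index[empty])}")
        counts = counts[~empty]
    return counts.div(counts.sum(axis=1), axis=0)


def correlate_proportion(
    proportions: pd.DataFrame, covariate: pd.Series
) -> pd.DataFrame:
    """Spearman rank correlation of each cluster's proportion vs a donor covariate."""
    cov = covariate.loc[proportions.index].astype(float)
    rows = {}
    for cluster in proportions.columns:
        rho, p = st.spearmanr(proportions[cluster], cov)
        rows[cluster] = {"rho": rho, "pval": p}
    return pd.DataFrame.from_dict(rows, orient="index")
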