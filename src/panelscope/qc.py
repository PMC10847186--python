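"""Cell-level quality control, normalization, and a test-only reference clusterer.

QC keeps a cell when all three hold (boundaries inclusive: the exclusion
criteria are strictly "less than 500", "more than 7000" detected genes and
"more than 20%" mitochondrial counts, so 500, 7000 and exactly 20% survive):

* detected genes (count > 0) within [min_genes, max_genes];
* mitochondrial count fraction <= max_mito_frac, with mitochondrial genes
  identified by a configurable symbol prefix (default ``"MT-"``).

Normalization is the scanpy default for this tool family: per-cell
library-size scaling to ``scale_total`` followed by log1p.  Raw counts are
preserved in ``layers["counts"]``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

from .matrix import COUNTS_LAYER, NORMALIZED_FLAG, SUBSET_KEY, counts_matrix, validate_labeled

__all__ = ["QCError", "qc_filter", "normalize", "reference_cluster"]


class QCError(RuntimeError):
    pass


def _per_cell_stats(X, var_names, mito_prefix: str):
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    total = np.asarray(X.sum(axis=1)).ravel().astype(float)
    mito_mask = np.array([g.startswith(mito_prefix) for g in var_names], dtype=bool)
    if mito_mask.any():
        mito = np.asarray(X[:, mito_mask].sum(axis=1)).ravel().astype(float)
    else:
        mito = np.zeros_like(total)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito / np.maximum(total, 1e-300), 0.0)
    return detected, total, mito_frac


def qc_filter(
    adata: AnnData,
    min_genes: int = 500,
    max_genes: int = 7000,
    max_mito_frac: float = 0.20,
    mito_prefix: str = "MT-",
) -> tuple[AnnData, pd.DataFrame]:
    """Filter cells on detected-gene count and mitochondrial fraction.

    Returns the filtered matrix and an exclusion report (one row per removed
    cell, with the first triggered reason among ``low_genes``, ``high_genes``,
    ``high_mito``).  Raises :class:`QCError` naming the dominant reason if no
    cell survives.  Idempotent: re-filtering the output removes nothing.
    """
    validate_labeled(adata)
    X = counts_matrix(adata)
    detected, _, mito_frac = _per_cell_stats(X, list(adata.var_names), mito_prefix)

    reasons = np.full(adata.n_obs, "", dtype=object)
    reasons[np.asarray(mito_frac > max_mito_frac)] = "high_mito"
    reasons[np.asarray(detected > max_genes)] = "high_genes"
    reasons[np.asarray(detected < min_genes)] = "low_genes"  # first-reason priority
    keep = reasons == ""

    report = pd.DataFrame(
        {
            "cell_id": np.asarray(adata.obs_names)[~keep],
            "reason": reasons[~keep],
            "detected_genes": detected[~keep],
            "mito_frac": mito_frac[~keep],
        }
    )
    if not keep.any():
        dominant = report["reason"].mode().iat[0]
        raise QCError(f"QC removed all {adata.n_obs} cells (dominant reason: {dominant})")
    return adata[keep].copy(), report


def normalize(adata: AnnData, scale_total: float = 1e4, *, on_normalized: str = "error") -> AnnData:
    """Library-size normalize to ``scale_total`` per cell, then log1p.

    The counts layer is preserved unchanged.  Calling normalize on an already
    normalized matrix raises by default (``on_normalized="noop"`` returns it
    untouched instead).  Cells with zero total counts are a hard error: they
    should have been removed by QC.
    """
    if adata.uns.get(NORMALIZED_FLAG, False):
        if on_normalized == "noop":
            return adata
        raise QCError("matrix is already normalized (pass on_normalized='noop' to skip)")
    X = adata.X
    total = np.asarray(X.sum(axis=1)).ravel().astype(float)
    if (total <= 0).any():
        bad = list(np.asarray(adata.obs_names)[total <= 0][:5])
        raise QCError(f"zero-count cells present (should have been QC-filtered): {bad}")

    adata = adata.copy()
    adata.layers[COUNTS_LAYER] = adata.X.copy()
    import scanpy as sc

    adata.X = adata.X.astype(np.float32)
    sc.pp.normalize_total(adata, target_sum=scale_total)
    sc.pp.log1p(adata)
    adata.uns[NORMALIZED_FLAG] = True
    return adata


def reference_cluster(adata: AnnData, k: int, seed: int) -> pd.Series:
    """Deterministic PCA + k-means labels ``c0..c{k-1}`` for test/synthetic flows.

    Not a stand-in for a real clustering workflow; it exists so the pipeline
    can be exercised end to end when no external labels are supplied.
    """
    if not adata.uns.get(NORMALIZED_FLAG, False):
        raise QCError("reference_cluster requires a normalized matrix")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > adata.n_obs:
        raise ValueError(f"k={k} exceeds number of cells ({adata.n_obs})")
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
    n_comp = min(20, X.shape[0] - 1, X.shape[1] - 1)
    if n_comp >= 2 and k > 1:
        X = PCA(n_components=n_comp, random_state=seed).fit_transform(X)
    labels = KMeans(n_clusters=k, n_init=10, random_state=seed).fit_predict(X)
    return pd.Series([f"c{i}" for i in labels], index=adata.obs_names, name=SUBSET_KEY)
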