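"""Labeled expression-matrix container and on-disk formats.

The in-memory container is an :class:`anndata.AnnData` with a fixed contract:

* ``X`` — raw integer counts on input; after :func:`panelscope.qc.normalize`
  it holds log-normalized values while the raw counts are preserved in
  ``layers["counts"]``.
* ``obs["subset"]`` — per-cell subset/cluster label (non-empty string).
* ``obs["sample"]`` — per-cell sample identifier (defaults to ``"s0"``).

On disk, a labeled matrix is either a Matrix Market directory
(``matrix.mtx`` genes x cells, ``features.tsv``, ``barcodes.tsv``,
``labels.tsv``) or a dense TSV (cells x genes) plus a two/three-column
labels TSV (cell_id, subset[, sample]).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

SUBSET_KEY = "subset"
SAMPLE_KEY = "sample"
COUNTS_LAYER = "counts"
NORMALIZED_FLAG = "panelscope_normalized"

__all__ = [
    "SUBSET_KEY",
    "SAMPLE_KEY",
    "COUNTS_LAYER",
    "make_labeled",
    "validate_labeled",
    "counts_matrix",
    "read_labeled",
    "write_labeled",
]


def make_labeled(
    counts,
    gene_ids,
    cell_ids,
    subsets,
    samples=None,
) -> AnnData:
    """Assemble a labeled AnnData from counts (cells x genes) and labels."""
    X = counts if sp.issparse(counts) else np.asarray(counts)
    obs = pd.DataFrame(index=pd.Index([str(c) for c in cell_ids], name="cell_id"))
    obs[SUBSET_KEY] = [str(s) for s in subsets]
    if samples is None:
        obs[SAMPLE_KEY] = "s0"
    else:
        obs[SAMPLE_KEY] = [str(s) for s in samples]
    var = pd.DataFrame(index=pd.Index([str(g) for g in gene_ids], name="gene_id"))
    adata = AnnData(X=X, obs=obs, var=var)
    validate_labeled(adata)
    return adata


def _dense(x) -> np.ndarray:
    return x.toarray() if sp.issparse(x) else np.asarray(x)


def counts_matrix(adata: AnnData):
    """Return the raw counts (the counts layer if present, else X)."""
    return adata.layers[COUNTS_LAYER] if COUNTS_LAYER in adata.layers else adata.X


def validate_labeled(adata: AnnData, *, require_counts: bool = True) -> None:
    if SUBSET_KEY not in adata.obs:
        raise ValueError(f"obs[{SUBSET_KEY!r}] is required")
    labels = adata.obs[SUBSET_KEY].astype(str)
    if (labels.str.len() == 0).any():
        raise ValueError("subset labels must be non-empty strings")
    if require_counts:
        X = counts_matrix(adata)
        data = np.asarray(X.data if sp.issparse(X) else X)
        if data.size and (data < 0).any():
            raise ValueError("counts must be non-negative")
        # integer dtypes are integral by construction
        if data.size and not np.issubdtype(data.dtype, np.integer) and np.any(np.mod(data, 1) != 0):
            raise ValueError("counts must be integral")


def write_labeled(adata: AnnData, outdir: str | Path, fmt: str = "mtx") -> Path:
    """Write counts + labels to ``outdir`` in ``mtx`` or dense ``tsv`` format."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    counts = counts_matrix(adata)
    labels = adata.obs[[SUBSET_KEY, SAMPLE_KEY]].copy()
    labels.index.name = "cell_id"
    if fmt == "mtx":
        scipy.io.mmwrite(outdir / "matrix.mtx", sp.coo_matrix(_dense(counts).T.astype(np.int64)))
        (outdir / "features.tsv").write_text("\n".join(adata.var_names) + "\n", encoding="utf-8")
        (outdir / "barcodes.tsv").write_text("\n".join(adata.obs_names) + "\n", encoding="utf-8")
    elif fmt == "tsv":
        pd.DataFrame(_dense(counts), index=adata.obs_names, columns=adata.var_names).to_csv(
            outdir / "matrix.tsv", sep="\t"
        )
    else:
        raise ValueError(f"unknown format {fmt!r}")
    labels.to_csv(outdir / "labels.tsv", sep="\t")
    return outdir


def read_labeled(indir: str | Path) -> AnnData:
    """Read a matrix written by :func:`write_labeled` (auto-detects format)."""
    indir = Path(indir)
    labels = pd.read_csv(indir / "labels.tsv", sep="\t", index_col=0, dtype=str)
    if (indir / "matrix.mtx").exists():
        mat = scipy.io.mmread(indir / "matrix.mtx").tocsr().T  # stored genes x cells
        genes = (indir / "features.tsv").read_text(encoding="utf-8").splitlines()
        cells = (indir / "barcodes.tsv").read_text(encoding="utf-8").splitlines()
    elif (indir / "matrix.tsv").exists():
        frame = pd.read_csv(indir / "matrix.tsv", sep="\t", index_col=0)
        mat = frame.to_numpy()
        genes = list(frame.columns)
        cells = [str(c) for c in frame.index]
    else:
        raise FileNotFoundError(f"no matrix.mtx or matrix.tsv under {indir}")
    labels = labels.reindex(cells)
    if labels[SUBSET_KEY].isna().any():
        missing = labels.index[labels[SUBSET_KEY].isna()][:5].tolist()
        raise ValueError(f"labels.tsv is missing subset labels for cells {missing}")
    samples = labels[SAMPLE_KEY] if SAMPLE_KEY in labels else None
    return make_labeled(mat, genes, cells, labels[SUBSET_KEY], samples)
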