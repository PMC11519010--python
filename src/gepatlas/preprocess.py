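"""Quality-control filters, TP10K log-normalisation and pseudobulking.

Cells expressing fewer than 500 genes or with a mitochondrial count
fraction above 60% are removed; genes detected in fewer than three cells
are removed. The boundaries are removal conditions, so a cell with exactly
500 detected genes or exactly 60% mitochondrial counts is retained.
Normalisation scales each cell to 10,000 total counts before ``log1p``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp
from anndata import AnnData

logger = logging.getLogger(__name__)

__all__ = ["filter_cells", "filter_genes", "normalize_tp10k_log", "pseudobulk"]


def _counts(adata: AnnData) -> sp.csr_matrix:
    X = adata.X
    return X.tocsr() if sp.issparse(X) else sp.csr_matrix(X)


def filter_cells(
    adata: AnnData, min_genes: int = 500, max_mito: float = 0.60
) -> AnnData:
    """Drop cells detecting fewer than ``min_genes`` genes or exceeding the
    mitochondrial fraction cutoff. Order of retained cells is preserved.
    """
    if min_genes <= 0 or max_mito <= 0:
        raise ValueError("thresholds must be positive")
    mito = adata.obs["mito_fraction"].to_numpy()
    if ((mito < 0) | (mito > 1)).any():
        raise ValueError("mito_fraction values must lie in [0, 1]")
    X = _counts(adata)
    detected = np.asarray((X > 0).sum(axis=1)).ravel()
    keep = (detected >= min_genes) & (mito <= max_mito)
    n_removed = int((~keep).sum())
    if n_removed:
        logger.warning("filter_cells removed %d of %d cells", n_removed, adata.n_obs)
    out = adata[keep].copy()
    out.obs["n_genes_detected"] = detected[keep]
    return out


def filter_genes(adata: AnnData, min_cells: int = 3) -> AnnData:
    """Drop genes detected (nonzero) in fewer than ``min_cells`` cells and
    recompute per-cell detected-gene counts."""
    X = _counts(adata)
    n_cells_per_gene = np.asarray((X > 0).sum(axis=0)).ravel()
    keep = n_cells_per_gene >= min_cells
    n_removed = int((~keep).sum())
    if n_removed:
        logger.warning("filter_genes removed %d of %d genes", n_removed, adata.n_vars)
    out = adata[:, keep].copy()
    out.obs["n_genes_detected"] = np.asarray((_counts(out) > 0).sum(axis=1)).ravel()
    return out


def normalize_tp10k_log(adata: AnnData) -> np.ndarray:
    """Per-cell transcripts-per-10,000 followed by natural-log ``log1p``.

    Entry (c, g) is ``ln(1 + 1e4 * count / total_c)``; before the log, each
    row sums to exactly 10,000.
    """
    X = _counts(adata).astype(float)
    totals = np.asarray(X.sum(axis=1)).ravel()
    zero = np.where(totals == 0)[0]
    if zero.size:
        names = adata.obs_names[zero[:5]].tolist()
        raise ValueError(f"cells with zero total counts (filter first): {names}")
    scaled = X.multiply(1e4 / totals[:, None]).toarray()
    return np.log1p(scaled)


def pseudobulk(
    adata: AnnData, by: str = "sample_id", sample_ids: list[str] | None = None
) -> pd.DataFrame:
    """Sum counts over cells per sample, giving a samples x genes table.

    ``sample_ids`` optionally fixes the row order / universe; any cell whose
    label is outside it raises.
    """
    labels = adata.obs[by].astype(str)
    if sample_ids is None:
        sample_ids = list(pd.unique(labels))
    else:
        unknown = set(labels) - set(sample_ids)
        if unknown:
            raise ValueError(f"cells mapped to unknown sample ids: {sorted(unknown)[:5]}")
    X = _counts(adata)
    index = pd.Index(sample_ids, name=by)
    codes = index.get_indexer(labels)
    # indicator^T @ X sums rows per sample without densifying
    ind = sp.csr_matrix(
        (np.ones(adata.n_obs), (codes, np.arange(adata.n_obs))),
        shape=(len(sample_ids), adata.n_obs),
    )
    agg = np.asarray((ind @ X).todense())
    return pd.DataFrame(agg.astype(np.int64), index=index, columns=adata.var_names)
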