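"""Projection of fixed GEP spectra onto external expression matrices.

Given reference spectra ``H`` (GEPs x genes) learned from single-cell data
and an external samples x genes matrix (bulk RNA-seq, spatial region
profiles), the shared genes are intersected and each external sample's GEP
usage is obtained by non-negative least squares against the *fixed*
spectra: ``w_s = argmin_{w >= 0} || x_s - w H ||_2``. Holding H fixed (as
opposed to warm-starting a free factorisation) guarantees the projected
usages refer to the same programmes that were discovered upstream.

Input matrices are used on whatever normalised scale they arrive on; the
fit is scale-equivariant, and the caller's scale is recorded in the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import kruskal, mannwhitneyu

from .cnmf import nnls_usages
from .hubs import bh_adjust

logger = logging.getLogger(__name__)

__all__ = ["ProjectionResult", "project_geps", "summarise_projection_by_group"]


@dataclass
class ProjectionResult:
    W_projected: pd.DataFrame  # samples x k, non-negative
    genes_used: list[str]
    genes_dropped: int  # genes of H absent from the expression matrix
    residual_norm: pd.Series  # per-sample ||x - wH||_2
    input_scale: str = "unspecified"


def project_geps(
    H: pd.DataFrame | np.ndarray,
    X_bulk: pd.DataFrame | np.ndarray,
    input_scale: str = "unspecified",
) -> ProjectionResult:
    """Project samples onto fixed spectra by per-sample NNLS.

    With DataFrames, genes are intersected by name (in H's gene order);
    with bare arrays the columns are assumed aligned. Negative expression
    entries are clamped to zero with a logged count.
    """
    if isinstance(H, pd.DataFrame) and isinstance(X_bulk, pd.DataFrame):
        shared = [g for g in H.columns if g in set(X_bulk.columns)]
        dropped = H.shape[1] - len(shared)
        gep_ids = list(H.index)
        sample_ids = list(X_bulk.index)
        Hm = H[shared].to_numpy(dtype=float)
        Xm = X_bulk[shared].to_numpy(dtype=float)
    else:
        H = np.asarray(H, dtype=float)
        Xm = np.asarray(X_bulk, dtype=float)
        if H.shape[1] != Xm.shape[1]:
            raise ValueError("array inputs must share the gene axis")
        shared = list(range(H.shape[1]))
        dropped = 0
        gep_ids = [f"GEP{i + 1}" for i in range(H.shape[0])]
        sample_ids = list(range(Xm.shape[0]))
        Hm = H
    k = Hm.shape[0]
    if len(shared) < k:
        raise ValueError(
            f"only {len(shared)} shared genes for {k} GEPs; cannot project"
        )
    n_neg = int((Xm < 0).sum())
    if n_neg:
        logger.warning("clamping %d negative expression entries to zero", n_neg)
        Xm = np.clip(Xm, 0.0, None)
    zero_rows = np.where(Xm.sum(axis=1) == 0)[0]
    if zero_rows.size:
        logger.warning("%d all-zero samples projected to zero usage", zero_rows.size)
    W = nnls_usages(Xm, Hm)
    resid = np.linalg.norm(Xm - W @ Hm, axis=1)
    return ProjectionResult(
        W_projected=pd.DataFrame(W, index=sample_ids, columns=gep_ids),
        genes_used=[str(g) for g in shared],
        genes_dropped=int(dropped),
        residual_norm=pd.Series(resid, index=sample_ids, name="residual_norm"),
        input_scale=input_scale,
    )


def summarise_projection_by_group(
    W_projected: pd.DataFrame,
    groups: pd.Series,
    fdr: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Kruskal-Wallis test of projected usage across groups per GEP, with
    pairwise Wilcoxon rank-sum follow-up for the significant GEPs only.

    Groups with fewer than two samples are excluded with a warning. BH
    correction is applied within the Kruskal-Wallis family and, separately,
    within the pairwise family.
    """
    groups = groups.loc[W_projected.index]
    sizes = groups.value_counts()
    small = sizes[sizes < 2]
    if len(small):
        logger.warning("excluding groups with < 2 samples: %s", list(small.index))
        keep = ~groups.isin(small.index)
        W_projected, groups = W_projected[keep], groups[keep]
    levels = sorted(pd.unique(groups.astype(str)))
    if len(levels) < 2:
        raise ValueError("need at least 2 groups of size >= 2")

    kw_rows = []
    for gep in W_projected.columns:
        vals = [W_projected.loc[groups.astype(str) == g, gep].to_numpy() for g in levels]
        if all(np.ptp(np.concatenate(vals)) == 0 for _ in (0,)):
            kw_rows.append({"gep_id": gep, "statistic": 0.0, "p_value": 1.0})
            continue
        stat, p = kruskal(*vals)
        kw_rows.append({"gep_id": gep, "statistic": float(stat), "p_value": float(p)})
    kw = pd.DataFrame(kw_rows).set_index("gep_id")
    adj, sig = bh_adjust(kw["p_value"].to_numpy(), fdr=fdr)
    kw["p_adjusted"], kw["significant"] = adj, sig

    pw_rows = []
    for gep in kw.index[kw["significant"]]:
        for a, b in combinations(levels, 2):
            xa = W_projected.loc[groups.astype(str) == a, gep].to_numpy()
            xb = W_projected.loc[groups.astype(str) == b, gep].to_numpy()
            stat, p = mannwhitneyu(xa, xb, alternative="two-sided")
            pw_rows.append(
                {"gep_id": gep, "group_a": a, "group_b": b,
                 "statistic": float(stat), "p_value": float(p),
                 "median_diff": float(np.median(xa) - np.median(xb))}
            )
    pairwise = pd.DataFrame(
        pw_rows, columns=["gep_id", "group_a", "group_b", "statistic",
                          "p_value", "median_diff"]
    )
    if len(pairwise):
        adj, sig = bh_adjust(pairwise["p_value"].to_numpy(), fdr=fdr)
        pairwise["p_adjusted"], pairwise["significant"] = adj, sig
    return kw, pairwise
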