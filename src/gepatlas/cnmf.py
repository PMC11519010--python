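"""Consensus non-negative matrix factorisation of gene expression programmes.

A count (or normalised) matrix ``X`` (cells x genes) is factorised many
times from random initialisations; the pooled, L2-normalised spectra are
cleaned of outlier components (by nearest-neighbour distance), clustered
into ``k`` groups, and each group's median spectrum becomes a consensus
GEP. Usages are then refit per cell by non-negative least squares against
the fixed consensus spectra. ``k`` is chosen by the silhouette of the
pooled-spectra clustering, with the Frobenius reconstruction error as a
tie-breaker; which solution is biologically meaningful remains a judgement
call, so the diagnostics for every ``k`` are returned for review.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment, nnls
from sklearn.cluster import KMeans
from sklearn.decomposition import non_negative_factorization
from sklearn.metrics import silhouette_score

__all__ = [
    "GEPModel",
    "factorize_once",
    "consensus_factorize",
    "select_k",
    "gep_gene_scores",
    "nnls_usages",
    "match_spectra",
]


@dataclass
class GEPModel:
    """Consensus factorisation result for one compartment."""

    k: int
    H: np.ndarray  # k x genes, rows unit L2 norm
    W: np.ndarray  # cells x k, NNLS refit against H
    silhouette: float
    frobenius_error: float  # ||X - WH||_F / ||X||_F
    outlier_mask: np.ndarray  # bool over pooled restart components
    solver: str = "cd"
    gene_scores: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if (self.H < 0).any() or (self.W < 0).any():
            raise ValueError("spectra and usages must be non-negative")
        if (self.H.sum(axis=1) == 0).any():
            raise ValueError("all-zero GEP spectrum")


def factorize_once(
    X: np.ndarray, k: int, seed: int, max_iter: int = 500, tol: float = 1e-6
) -> tuple[np.ndarray, np.ndarray]:
    """One Frobenius NMF run (coordinate descent, seeded random init)."""
    X = np.asarray(X, dtype=float)
    if k >= min(X.shape):
        raise ValueError(f"k={k} out of range for matrix of shape {X.shape}")
    W, H, _ = non_negative_factorization(
        X,
        n_components=k,
        init="random",
        solver="cd",
        beta_loss="frobenius",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    return W, H


def nnls_usages(X: np.ndarray, H: np.ndarray) -> np.ndarray:
    """Per-row non-negative least squares against fixed spectra.

    Row i solves ``argmin_{w >= 0} || X[i] - w @ H ||_2`` exactly (active-set
    NNLS), so fixed spectra are never perturbed by the fit.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Ht = np.asarray(H, dtype=float).T  # genes x k
    W = np.empty((X.shape[0], H.shape[0]))
    for i in range(X.shape[0]):
        W[i], _ = nnls(Ht, X[i])
    return W


def _pooled_spectra(
    X: np.ndarray, k: int, n_restarts: int, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Stack L2-normalised spectra from all restarts; returns (pool, restart id)."""
    rows, origin = [], []
    for r in range(n_restarts):
        _, H = factorize_once(X, k, seed=seed + r)
        norms = np.linalg.norm(H, axis=1)
        norms[norms == 0] = 1.0
        rows.append(H / norms[:, None])
        origin.extend([r] * k)
    return np.vstack(rows), np.asarray(origin)


def _nn_distances(pool: np.ndarray, origin: np.ndarray) -> np.ndarray:
    """Distance from each pooled component to its nearest neighbour from a
    *different* restart (same-restart neighbours would mask a rogue restart
    whose components resemble each other)."""
    d2 = (
        np.sum(pool**2, axis=1)[:, None]
        + np.sum(pool**2, axis=1)[None, :]
        - 2 * pool @ pool.T
    )
    np.clip(d2, 0, None, out=d2)
    same = origin[:, None] == origin[None, :]
    d2[same] = np.inf
    return np.sqrt(d2.min(axis=1))


def consensus_factorize(
    X: np.ndarray,
    k: int,
    n_restarts: int = 30,
    outlier_distance_threshold: float | None = None,
    seed: int = 0,
) -> GEPModel:
    """Pool restarts, drop outlier components, cluster, take medians, refit.

    ``outlier_distance_threshold`` defaults to the 95th percentile of
    nearest-neighbour distances — an automated stand-in for choosing the
    cutoff from the distance histogram by eye.
    """
    if n_restarts < 10:
        raise ValueError("n_restarts must be >= 10 for a meaningful consensus")
    X = np.asarray(X, dtype=float)
    pool, origin = _pooled_spectra(X, k, n_restarts, seed)
    nn_dist = _nn_distances(pool, origin)
    thr = (
        float(np.quantile(nn_dist, 0.95))
        if outlier_distance_threshold is None
        else float(outlier_distance_threshold)
    )
    outlier = nn_dist > thr
    survivors = pool[~outlier]
    if survivors.shape[0] < k:
        raise ValueError(
            "outlier filtering left fewer components than clusters; "
            "relax outlier_distance_threshold"
        )
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    labels = km.fit_predict(survivors)
    if len(np.unique(labels)) < k:
        raise ValueError(
            "empty consensus cluster after outlier filtering; "
            "relax outlier_distance_threshold"
        )
    H = np.vstack(
        [np.median(survivors[labels == c], axis=0) for c in range(k)]
    )
    norms = np.linalg.norm(H, axis=1)
    if (norms == 0).any():
        raise ValueError("degenerate all-zero consensus spectrum")
    H /= norms[:, None]
    W = nnls_usages(X, H)
    sil = (
        float(silhouette_score(survivors, labels))
        if k > 1 and survivors.shape[0] > k
        else float("nan")
    )
    err = float(np.linalg.norm(X - W @ H) / np.linalg.norm(X))
    return GEPModel(
        k=k,
        H=H,
        W=W,
        silhouette=sil,
        frobenius_error=err,
        outlier_mask=outlier,
    )


def select_k(
    X: np.ndarray,
    k_range: range | list[int],
    n_restarts: int = 30,
    seed: int = 0,
    silhouette_tol: float = 0.01,
    error_improvement: float = 0.05,
) -> tuple[int, pd.DataFrame]:
    """Consensus diagnostics over a range of ``k``.

    Stability and fit are read jointly: every ``k`` whose silhouette lies
    within ``silhouette_tol`` of the maximum is a stability tie, and within
    the tie the smallest ``k`` is kept unless a larger one lowers the
    relative Frobenius error by more than ``error_improvement`` (near-
    stable solutions routinely differ by silhouette noise while the error
    still falls sharply up to the true rank). The returned table carries
    both diagnostics per ``k`` for human review.
    """
    ks = list(k_range)
    if not ks:
        raise ValueError("k_range must be non-empty")
    if min(ks) < 2:
        raise ValueError("k must be >= 2 (silhouette undefined at k=1)")
    rows = []
    for k in ks:
        model = consensus_factorize(X, k, n_restarts=n_restarts, seed=seed)
        rows.append(
            {"k": k, "silhouette": model.silhouette, "frobenius_error": model.frobenius_error}
        )
    diag = pd.DataFrame(rows).set_index("k")
    tied = diag[diag["silhouette"] >= diag["silhouette"].max() - silhouette_tol]
    k_selected = int(tied.index[0])
    best_err = float(tied["frobenius_error"].iloc[0])
    for k, err in tied["frobenius_error"].iloc[1:].items():
        if err < best_err * (1.0 - error_improvement):
            k_selected, best_err = int(k), float(err)
    return k_selected, diag


def gep_gene_scores(X_z: np.ndarray, W_consensus: np.ndarray) -> np.ndarray:
    """Joint multiple-regression gene scores: per gene, OLS of z-scored
    expression on all usage columns at once; returns k x genes coefficients.
    Top-weighted gene lists per GEP follow by ranking each row."""
    X_z = np.asarray(X_z, dtype=float)
    W = np.asarray(W_consensus, dtype=float)
    k = W.shape[1]
    if np.linalg.matrix_rank(W) < k:
        corr = np.corrcoef(W.T)
        bad = [
            (i, j)
            for i in range(k)
            for j in range(i + 1, k)
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"usage matrix is rank-deficient; collinear GEP pairs: {bad}")
    coef, *_ = np.linalg.lstsq(W, X_z, rcond=None)
    return coef  # k x genes


def match_spectra(
    H_est: np.ndarray, H_true: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Hungarian matching of estimated to reference spectra by cosine.

    Returns ``(perm, cosines)`` with ``H_est[perm[j]]`` matched to
    ``H_true[j]``; invariant to row scale.
    """
    A = np.asarray(H_est, float)
    B = np.asarray(H_true, float)
    A = A / np.linalg.norm(A, axis=1, keepdims=True)
    B = B / np.linalg.norm(B, axis=1, keepdims=True)
    cos = A @ B.T  # est x true
    ri, ci = linear_sum_assignment(-cos)
    perm = np.empty(B.shape[0], dtype=int)
    perm[ci] = ri
    return perm, cos[ri, ci][np.argsort(ci)]
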