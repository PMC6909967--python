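"""Similarity network fusion (SNF) of multiple circRNA similarity views.

Cross-diffusion over row-stochastic matrices: each view is normalized so
that rows sum to one with half the mass on the diagonal, a row-stochastic
K-nearest-neighbor kernel captures each view's locally reliable structure,
and the update P_v <- S_v (mean of other views' P) S_v^T diffuses each
view's status matrix through its own local graph. Entries outside a view's
KNN graph influence the result only through diffusion, never directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .io import SimilarityMatrix

logger = logging.getLogger("circboost")

__all__ = ["SNFParams", "normalize", "knn_kernel", "fuse"]


@dataclass(frozen=True)
class SNFParams:
    K: int = 20  # neighbor count (capped at n - 1)
    t: int = 20  # maximum diffusion iterations
    tol: float = 1e-6  # early-stop threshold on successive fused averages

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.t < 1:
            raise ValueError("t must be >= 1")


def normalize(W: np.ndarray | SimilarityMatrix) -> np.ndarray:
    """Row normalization with half the mass reserved for the diagonal.

    P(i,j) = W(i,j) / (2 * sum_{k != i} W(i,k)) for j != i and P(i,i) = 1/2,
    so every row sums to 1 regardless of the scale of W. A row with no
    off-diagonal mass collapses to P(i,i) = 1.
    """
    w = W.values if isinstance(W, SimilarityMatrix) else np.asarray(W, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("normalize expects a square matrix")
    if (w < 0).any():
        raise ValueError("normalize expects a non-negative matrix")
    n = w.shape[0]
    off = w.copy()
    np.fill_diagonal(off, 0.0)
    row = off.sum(axis=1)
    p = np.zeros_like(w)
    ok = row > 0
    p[ok] = off[ok] / (2.0 * row[ok, None])
    np.fill_diagonal(p, 0.5)
    if (~ok).any():
        logger.warning("%d row(s) with no off-diagonal mass in SNF normalize", int((~ok).sum()))
        for i in np.nonzero(~ok)[0]:
            p[i, :] = 0.0
            p[i, i] = 1.0
    return p


def knn_kernel(W: np.ndarray | SimilarityMatrix, K: int) -> np.ndarray:
    """Row-stochastic K-nearest-neighbor kernel.

    S(i,j) = W(i,j) / sum_{k in V(i)} W(i,k) for j in V(i), else 0, where
    V(i) holds the K most similar neighbors of i (self excluded). Ties at
    the K-th neighbor break toward the lower index.
    """
    w = W.values if isinstance(W, SimilarityMatrix) else np.asarray(W, dtype=float)
    n = w.shape[0]
    if not 1 <= K < n:
        raise ValueError(f"K must satisfy 1 <= K < n, got K={K}, n={n}")
    s = np.zeros_like(w)
    for i in range(n):
        row = w[i].copy()
        row[i] = -np.inf
        # stable sort on negated values: ties keep the lower index first
        order = np.argsort(-row, kind="stable")[:K]
        mass = w[i, order].sum()
        if mass > 0:
            s[i, order] = w[i, order] / mass
        else:
            s[i, i] = 1.0
    return s


def fuse(
    views: list[SimilarityMatrix], params: SNFParams | None = None
) -> SimilarityMatrix:
    """Fuse M >= 2 similarity views into one consensus SimilarityMatrix.

    Iterates P_v <- S_v @ mean_{u != v}(P_u) @ S_v.T with per-iteration
    symmetrization, stopping after ``t`` rounds or once the Frobenius
    distance between successive cross-view averages drops below ``tol``.
    The average of the final status matrices is max-rescaled off-diagonal
    and given a unit diagonal so the output honors the similarity contract.
    """
    params = params or SNFParams()
    if len(views) < 2:
        raise ValueError("need at least 2 views to fuse")
    ids = views[0].ids
    n = len(ids)
    for v in views[1:]:
        if v.ids != ids:
            raise ValueError("all views must share the same identifier order")
    k = min(params.K, n - 1)
    if k != params.K:
        logger.warning("SNF K reduced from %d to %d (n=%d)", params.K, k, n)
    p_list = [normalize(v.values) for v in views]
    s_list = [knn_kernel(p, k) for p in p_list]
    m = len(views)
    prev_avg = sum(p_list) / m
    for it in range(params.t):
        new_list = []
        for v in range(m):
            others = (sum(p_list) - p_list[v]) / (m - 1)
            p_new = s_list[v] @ others @ s_list[v].T
            # symmetrize, then renormalize: the diffusion product is not
            # row-stochastic by itself, and the row-sum contract (mass
            # non-explosion) requires restoring it every iteration
            new_list.append(normalize((p_new + p_new.T) / 2.0))
        p_list = new_list
        avg = sum(p_list) / m
        delta = float(np.linalg.norm(avg - prev_avg))
        prev_avg = avg
        if delta < params.tol:
            logger.debug("SNF converged after %d iteration(s), delta=%.3g", it + 1, delta)
            break
    fused = (prev_avg + prev_avg.T) / 2.0
    off_mask = ~np.eye(n, dtype=bool)
    max_off = fused[off_mask].max() if n > 1 else 0.0
    if max_off > 0:
        fused[off_mask] = fused[off_mask] / max_off
    np.fill_diagonal(fused, 1.0)
    fused = np.clip(fused, 0.0, 1.0)
    return SimilarityMatrix(list(ids), fused).validate()
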