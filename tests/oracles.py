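"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from the mathematical definition, deliberately
avoiding the code paths (and where possible the libraries) used by the
package itself.
"""

from __future__ import annotations

import itertools
from collections import deque

import numpy as np

NEG = -1e18


def nw_affine_score(
    a: str, b: str, match: float, mismatch: float, gap_open: float, gap_extend: float
) -> float:
    """Three-state Gotoh DP; a gap of length L costs gap_open + gap_extend*L."""
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b (vertical)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(gap_open + gap_extend * i)
    for j in range(1, m + 1):
        Iy[0, j] = -(gap_open + gap_extend * j)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i, j] = s + max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            Ix[i, j] = max(
                M[i - 1, j] - gap_open - gap_extend,
                Ix[i - 1, j] - gap_extend,
                Iy[i - 1, j] - gap_open - gap_extend,
            )
            Iy[i, j] = max(
                M[i, j - 1] - gap_open - gap_extend,
                Iy[i, j - 1] - gap_extend,
                Ix[i, j - 1] - gap_open - gap_extend,
            )
    return float(max(M[n, m], Ix[n, m], Iy[n, m]))


def pearson_two_pass(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook covariance / (sigma_x sigma_y), two explicit passes."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    cov = sum((a - mx) * (b - my) for a, b in zip(x, y)) / n
    sx = (sum((a - mx) ** 2 for a in x) / n) ** 0.5
    sy = (sum((b - my) ** 2 for b in y) / n) ** 0.5
    return cov / (sx * sy)


# ---------------------------------------------------------------------------
# Graph centralities by enumeration
# ---------------------------------------------------------------------------


def _bfs_shortest_paths(adj: np.ndarray, s: int):
    """Distances and shortest-path counts from source s (unweighted)."""
    n = adj.shape[0]
    dist = [-1] * n
    sigma = [0] * n
    dist[s] = 0
    sigma[s] = 1
    q = deque([s])
    order = []
    while q:
        u = q.popleft()
        order.append(u)
        for v in range(n):
            if adj[u, v]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    q.append(v)
                if dist[v] == dist[u] + 1:
                    sigma[v] += sigma[u]
        # note: sigma accumulation above counts each predecessor once because
        # v is examined from every neighbor u exactly once
    return dist, sigma


def betweenness_brute(adj: np.ndarray) -> np.ndarray:
    """Normalized betweenness by explicit enumeration of all shortest paths."""
    n = adj.shape[0]
    bc = np.zeros(n)

    def all_shortest_paths(s: int, t: int, dist) -> list[list[int]]:
        if dist[t] < 0:
            return []
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(path)
                return
            for v in range(n):
                if adj[u, v] and dist[v] == dist[u] + 1:
                    extend(path + [v])

        extend([s])
        return paths

    for s in range(n):
        dist, _ = _bfs_shortest_paths(adj, s)
        for t in range(s + 1, n):
            paths = all_shortest_paths(s, t, dist)
            if not paths:
                continue
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in paths if v in p)
                bc[v] += through / len(paths)
    denom = (n - 1) * (n - 2) / 2.0
    return bc / denom if denom > 0 else bc


def closeness_brute(adj: np.ndarray) -> np.ndarray:
    """Component-wise closeness scaled by (reachable)/(n-1)."""
    n = adj.shape[0]
    cc = np.zeros(n)
    for s in range(n):
        dist, _ = _bfs_shortest_paths(adj, s)
        reach = [d for d in dist if d > 0]
        if not reach:
            continue
        cc[s] = (len(reach) / sum(reach)) * (len(reach) / (n - 1))
    return cc


def eigenvector_power(adj: np.ndarray, iters: int = 100000) -> np.ndarray:
    """Principal eigenvector by power iteration from the ones vector.

    Iterates on A + I (same eigenvectors, shifted eigenvalues) so the
    iteration also converges on bipartite graphs, whose spectrum is
    symmetric about zero.
    """
    n = adj.shape[0]
    v = np.ones(n) / np.sqrt(n)
    for _ in range(iters):
        w = adj @ v + v
        norm = np.linalg.norm(w)
        if norm == 0:
            return v
        w = w / norm
        if np.linalg.norm(w - v) < 1e-15:
            return w
        v = w
    return v


# ---------------------------------------------------------------------------
# AUC by pair counting
# ---------------------------------------------------------------------------


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """(#{pos > neg} + 0.5 #{ties}) / (n_pos * n_neg), exhaustive."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Regression-tree split enumeration
# ---------------------------------------------------------------------------


def best_split_enumerate(X: np.ndarray, r: np.ndarray, min_leaf: int = 1):
    """Exhaustively enumerate every (feature, midpoint) split and return the
    one minimizing total child sum-of-squares; ties -> lowest feature index,
    then lowest threshold. Returns None if no split improves."""
    n, d = X.shape
    parent_sse = float(((r - r.mean()) ** 2).sum())
    best = None
    best_sse = parent_sse - 1e-12
    for f in range(d):
        values = sorted(set(X[:, f]))
        for lo, hi in zip(values[:-1], values[1:]):
            thr = (lo + hi) / 2.0
            left = r[X[:, f] <= thr]
            right = r[X[:, f] > thr]
            if len(left) < min_leaf or len(right) < min_leaf:
                continue
            sse = float(((left - left.mean()) ** 2).sum()) + float(
                ((right - right.mean()) ** 2).sum()
            )
            if sse < best_sse - 1e-15:
                best_sse = sse
                best = (f, thr)
    return best


# ---------------------------------------------------------------------------
# Dense SNF reference
# ---------------------------------------------------------------------------


def snf_reference(views: list[np.ndarray], K: int, t: int) -> np.ndarray:
    """Straightforward dense re-implementation of the cross-diffusion update."""

    def norm(w):
        n = w.shape[0]
        p = np.zeros_like(w)
        for i in range(n):
            s = sum(w[i, k] for k in range(n) if k != i)
            for j in range(n):
                if i == j:
                    p[i, j] = 0.5
                elif s > 0:
                    p[i, j] = w[i, j] / (2 * s)
            if s == 0:
                p[i, i] = 1.0
        return p

    def kernel(w, K):
        n = w.shape[0]
        s = np.zeros_like(w)
        for i in range(n):
            nb = sorted(
                (j for j in range(n) if j != i), key=lambda j: (-w[i, j], j)
            )[:K]
            tot = sum(w[i, j] for j in nb)
            for j in nb:
                s[i, j] = w[i, j] / tot if tot > 0 else 0.0
            if tot == 0:
                s[i, i] = 1.0
        return s

    ps = [norm(v) for v in views]
    ss = [kernel(p, K) for p in ps]
    m = len(views)
    for _ in range(t):
        new = []
        for v in range(m):
            others = sum(ps[u] for u in range(m) if u != v) / (m - 1)
            p = ss[v] @ others @ ss[v].T
            new.append(norm((p + p.T) / 2))
        ps = new
    return sum(ps) / m
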