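"""Per-pair feature engineering.

Each (circRNA, disease) pair is described by the concatenation
F = [F1(c), F1(d), F2(c), F2(d), F3(c), F4(c, d)] of four feature
categories:

* F1 — network statistics: association degree, mean similarity, and a
  histogram of the entity's similarity scores over [0, 1].
* F2 — graph-theory features of the mean-thresholded unweighted similarity
  graph: degree, top-N similarity scores, (weighted) averages of the F1
  blocks of the top-N neighbors, and betweenness / closeness / eigenvector
  centrality.
* F3 — sequence composition of the circRNA: GC fraction and k-mer
  frequency spectra (k = 2, 3, 4 by default). Diseases carry no sequence,
  so this block exists only on the circRNA side.
* F4 — association-network features of the pair: truncated-SVD latent
  vectors of both entities, association degrees, and centralities in the
  bipartite association graph.

A :class:`PairFeatureAssembler` precomputes everything that depends only on
the similarity matrices and sequences, so that the association-derived
blocks can be recomputed cheaply per cross-validation fold with the
held-out association masked.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from sklearn.decomposition import PCA

from .io import AssociationMatrix, SimilarityMatrix

logger = logging.getLogger("circboost")

__all__ = [
    "FeatureConfig",
    "PairFeatureAssembler",
    "PCAProjection",
    "f1_statistics",
    "f3_sequence",
    "f4_association",
    "centralities_from_adjacency",
    "pca_reduce",
]


@dataclass(frozen=True)
class FeatureConfig:
    n_bins: int = 10          # histogram bins for similarity distributions
    top_n: int = 10           # neighbor count for the F2 top-similarity block
    kmer_ks: tuple[int, ...] = (2, 3, 4)
    svd_rank: int = 5         # latent dimension of the association SVD
    pca_variance: float = 0.95  # retained variance fraction (or int component count)
    kmer_raw: bool = False    # True: raw k-mer counts instead of frequencies

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if self.top_n < 1:
            raise ValueError("top_n must be >= 1")
        if any(k < 1 for k in self.kmer_ks):
            raise ValueError("each k-mer k must be >= 1")
        if self.svd_rank < 1:
            raise ValueError("svd_rank must be >= 1")
        if isinstance(self.pca_variance, float) and not 0 < self.pca_variance <= 1:
            raise ValueError("fractional pca_variance must lie in (0, 1]")


# ---------------------------------------------------------------------------
# Centralities
# ---------------------------------------------------------------------------


def centralities_from_adjacency(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Betweenness, closeness, and eigenvector centrality of an undirected
    unweighted graph given by a 0/1 adjacency matrix.

    Betweenness is pair-normalized; closeness is computed within each
    connected component and scaled by (component size - 1)/(n - 1);
    eigenvector centrality is the principal eigenvector of the adjacency
    matrix (unit L2 norm, non-negative).
    """
    n = adj.shape[0]
    g = nx.from_numpy_array(adj)
    bc = nx.betweenness_centrality(g, normalized=True)
    cc = nx.closeness_centrality(g, wf_improved=True)
    bc_arr = np.array([bc[i] for i in range(n)])
    cc_arr = np.array([cc[i] for i in range(n)])
    if adj.any():
        evals, evecs = np.linalg.eigh(adj)
        vec = evecs[:, -1]
        if vec.sum() < 0:
            vec = -vec
        vec = np.clip(vec, 0.0, None)
        norm = np.linalg.norm(vec)
        ec_arr = vec / norm if norm > 0 else np.full(n, 1.0 / np.sqrt(n))
    else:
        ec_arr = np.full(n, 1.0 / np.sqrt(n))
    return bc_arr, cc_arr, ec_arr


# ---------------------------------------------------------------------------
# F1 / F2 similarity-side blocks
# ---------------------------------------------------------------------------


def _sim_stats(values: np.ndarray, cfg: FeatureConfig) -> np.ndarray:
    """Per-entity [mean off-diagonal similarity, n_bins histogram counts].

    Histogram bins partition [0, 1] left-closed, with the last bin closed on
    both sides, so counts always sum to n - 1.
    """
    n = values.shape[0]
    off_mask = ~np.eye(n, dtype=bool)
    edges = np.linspace(0.0, 1.0, cfg.n_bins + 1)
    out = np.zeros((n, 1 + cfg.n_bins))
    for i in range(n):
        row = values[i, off_mask[i]]
        out[i, 0] = row.mean() if row.size else 0.0
        out[i, 1:], _ = np.histogram(row, bins=edges)
    return out


def f1_statistics(
    sim: SimilarityMatrix, degrees: np.ndarray, cfg: FeatureConfig
) -> np.ndarray:
    """F1 block for every entity of one side: [degree, mean sim, histogram]."""
    stats = _sim_stats(sim.values, cfg)
    return np.column_stack([np.asarray(degrees, dtype=float), stats])


@dataclass
class _GraphSide:
    """Static F2 machinery for one similarity matrix."""

    uw_degree: np.ndarray          # degree in the mean-thresholded graph
    top_sims: np.ndarray           # (n, top_n) descending, zero-padded
    navg: np.ndarray               # (n, n) row-stochastic top-N averaging matrix
    wavg: np.ndarray               # (n, n) similarity-weighted averaging matrix
    bc: np.ndarray
    cc: np.ndarray
    ec: np.ndarray


def _graph_side(values: np.ndarray, cfg: FeatureConfig) -> _GraphSide:
    n = values.shape[0]
    off_mask = ~np.eye(n, dtype=bool)
    mean_off = values[off_mask].mean() if n > 1 else 0.0
    adj = ((values > mean_off) & off_mask).astype(float)
    adj = np.maximum(adj, adj.T)  # symmetric input keeps this a no-op
    bc, cc, ec = centralities_from_adjacency(adj)
    top_sims = np.zeros((n, cfg.top_n))
    navg = np.zeros((n, n))
    wavg = np.zeros((n, n))
    for i in range(n):
        row = values[i].copy()
        row[i] = -np.inf
        order = np.argsort(-row, kind="stable")[: min(cfg.top_n, n - 1)]
        sims = values[i, order]
        top_sims[i, : len(order)] = sims
        if len(order):
            navg[i, order] = 1.0 / len(order)
            mass = sims.sum()
            if mass > 0:
                wavg[i, order] = sims / mass
    return _GraphSide(adj.sum(axis=1), top_sims, navg, wavg, bc, cc, ec)


# ---------------------------------------------------------------------------
# F3 sequence block
# ---------------------------------------------------------------------------


def _kmer_index(k: int) -> dict[str, int]:
    return {"".join(p): i for i, p in enumerate(itertools.product("ACGT", repeat=k))}


def f3_sequence(seqs: dict[str, str], cfg: FeatureConfig, ids: list[str] | None = None) -> np.ndarray:
    """Per-circRNA [GC fraction, k-mer spectra for each k in kmer_ks].

    k-mer counts are normalized by (len - k + 1) unless ``kmer_raw``;
    sequences shorter than k yield an all-zero block for that k. k-mers
    containing non-ACGT characters are skipped.
    """
    ids = sorted(seqs) if ids is None else list(ids)
    width = 1 + sum(4**k for k in cfg.kmer_ks)
    out = np.zeros((len(ids), width))
    indexes = {k: _kmer_index(k) for k in cfg.kmer_ks}
    for row, name in enumerate(ids):
        seq = seqs[name]
        if not seq:
            raise ValueError(f"empty sequence for {name!r}")
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        out[row, 0] = gc
        offset = 1
        for k in cfg.kmer_ks:
            idx = indexes[k]
            n_pos = len(seq) - k + 1
            if n_pos < 1:
                logger.warning("sequence %r shorter than k=%d; zero k-mer block", name, k)
            else:
                counts = np.zeros(4**k)
                for p in range(n_pos):
                    kmer = seq[p : p + k]
                    j = idx.get(kmer)
                    if j is not None:
                        counts[j] += 1
                out[row, offset : offset + 4**k] = (
                    counts if cfg.kmer_raw else counts / n_pos
                )
            offset += 4**k
    return out


# ---------------------------------------------------------------------------
# F4 association block
# ---------------------------------------------------------------------------


def _truncated_svd_latents(A: np.ndarray, rank: int) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic rank-``rank`` latent factors U sqrt(S), V sqrt(S)."""
    r = min(rank, min(A.shape))
    if r < rank:
        logger.warning("svd_rank %d clipped to %d for matrix %s", rank, r, A.shape)
    u, s, vt = np.linalg.svd(A, full_matrices=False)
    u, s, vt = u[:, :r], s[:r], vt[:r]
    # sign fix: largest-|.| component of each left singular vector positive
    for k in range(r):
        pivot = np.argmax(np.abs(u[:, k]))
        if u[pivot, k] < 0:
            u[:, k] = -u[:, k]
            vt[k] = -vt[k]
    root = np.sqrt(s)
    return u * root, vt.T * root


@dataclass
class _F4Arrays:
    u: np.ndarray        # (n_c, rank) circRNA latents
    v: np.ndarray        # (n_d, rank) disease latents
    deg_c: np.ndarray
    deg_d: np.ndarray
    cent_c: np.ndarray   # (n_c, 3) betweenness, closeness, eigenvector
    cent_d: np.ndarray


def _f4_arrays(A: np.ndarray, cfg: FeatureConfig) -> _F4Arrays:
    n_c, n_d = A.shape
    u, v = _truncated_svd_latents(A, cfg.svd_rank)
    adj = np.zeros((n_c + n_d, n_c + n_d))
    adj[:n_c, n_c:] = A
    adj[n_c:, :n_c] = A.T
    bc, cc, ec = centralities_from_adjacency(adj)
    cent = np.column_stack([bc, cc, ec])
    return _F4Arrays(u, v, A.sum(axis=1), A.sum(axis=0), cent[:n_c], cent[n_c:])


def f4_association(
    A: AssociationMatrix, pairs: list[tuple[int, int]], cfg: FeatureConfig | None = None
) -> np.ndarray:
    """F4 block for each (circ index, disease index) pair:
    [U_i, V_j, deg(i), deg(j), bc/cc/ec(i), bc/cc/ec(j)]."""
    cfg = cfg or FeatureConfig()
    arr = _f4_arrays(A.values, cfg)
    ci = np.array([p[0] for p in pairs])
    dj = np.array([p[1] for p in pairs])
    return np.hstack(
        [
            arr.u[ci],
            arr.v[dj],
            arr.deg_c[ci, None],
            arr.deg_d[dj, None],
            arr.cent_c[ci],
            arr.cent_d[dj],
        ]
    )


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


class PairFeatureAssembler:
    """Builds feature matrices for (circRNA, disease) index pairs.

    Everything derived from the fused circRNA similarity ``P``, the disease
    similarity ``DS``, and the sequences is precomputed once; blocks derived
    from the association matrix are recomputed on every call so that
    cross-validation can mask the held-out association.
    """

    def __init__(
        self,
        P: SimilarityMatrix,
        DS: SimilarityMatrix,
        seqs: dict[str, str],
        cfg: FeatureConfig | None = None,
    ) -> None:
        self.cfg = cfg or FeatureConfig()
        self.circ_ids = list(P.ids)
        self.disease_ids = list(DS.ids)
        missing = [c for c in self.circ_ids if c not in seqs]
        if missing:
            raise KeyError(f"sequences missing for circRNAs: {missing[:5]}")
        self._c_stats = _sim_stats(P.values, self.cfg)   # (n_c, 1 + n_bins)
        self._d_stats = _sim_stats(DS.values, self.cfg)
        self._c_graph = _graph_side(P.values, self.cfg)
        self._d_graph = _graph_side(DS.values, self.cfg)
        self._f3 = f3_sequence(seqs, self.cfg, ids=self.circ_ids)
        self.block_index = self._build_block_index()

    # -- layout -------------------------------------------------------------

    def _build_block_index(self) -> dict[str, slice]:
        nb = self.cfg.n_bins
        f1 = 2 + nb
        f2 = 1 + self.cfg.top_n + 2 * f1 + 3
        f3 = self._f3.shape[1]
        f4 = 2 * min(self.cfg.svd_rank, min(len(self.circ_ids), len(self.disease_ids))) + 8
        spans, start = {}, 0
        for name, width in [
            ("F1_circ", f1), ("F1_disease", f1),
            ("F2_circ", f2), ("F2_disease", f2),
            ("F3_circ", f3), ("F4_pair", f4),
        ]:
            spans[name] = slice(start, start + width)
            start += width
        self.n_features = start
        return spans

    def feature_names(self) -> list[str]:
        names: list[str] = []
        nb = self.cfg.n_bins
        for side in ("c", "d"):
            names += [f"F1.{side}.num.nei", f"F1.{side}.sim.ave"]
            names += [f"F1.{side}.dis.num.{b}" for b in range(nb)]
        for side in ("c", "d"):
            names += [f"F2.{side}.num.nei"]
            names += [f"F2.{side}.K.sim.{t}" for t in range(self.cfg.top_n)]
            names += [f"F2.{side}.ave.feat1.{t}" for t in range(2 + nb)]
            names += [f"F2.{side}.W.ave.feat1.{t}" for t in range(2 + nb)]
            names += [f"F2.{side}.bc", f"F2.{side}.cc", f"F2.{side}.ec"]
        names += ["F3.GC.Cont"]
        for k in self.cfg.kmer_ks:
            names += [f"F3.kmer{k}.{i}" for i in range(4**k)]
        rank = (self.block_index["F4_pair"].stop - self.block_index["F4_pair"].start - 8) // 2
        names += [f"F4.svd.c.{r}" for r in range(rank)]
        names += [f"F4.svd.d.{r}" for r in range(rank)]
        names += ["F4.c.d.num", "F4.d.c.num",
                  "F4.c.bc", "F4.c.cc", "F4.c.ec",
                  "F4.d.bc", "F4.d.cc", "F4.d.ec"]
        return names

    # -- assembly -----------------------------------------------------------

    def _side_blocks(
        self, stats: np.ndarray, graph: _GraphSide, degrees: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """(F1, F2) matrices for one side under the given association degrees."""
        f1 = np.column_stack([degrees, stats])
        f2 = np.column_stack(
            [
                graph.uw_degree,
                graph.top_sims,
                graph.navg @ f1,
                graph.wavg @ f1,
                graph.bc,
                graph.cc,
                graph.ec,
            ]
        )
        return f1, f2

    def _assoc_side_arrays(self, A_values: np.ndarray) -> tuple:
        """(F1c, F2c, F1d, F2d, f4 arrays) under one association matrix."""
        f1c, f2c = self._side_blocks(self._c_stats, self._c_graph, A_values.sum(axis=1))
        f1d, f2d = self._side_blocks(self._d_stats, self._d_graph, A_values.sum(axis=0))
        f4 = _f4_arrays(A_values, self.cfg)
        return f1c, f2c, f1d, f2d, f4

    def feature_matrix(
        self,
        pairs: list[tuple[int, int]] | np.ndarray,
        A_values: np.ndarray,
        mask: bool = True,
    ) -> np.ndarray:
        """Feature matrix (len(pairs) x n_features) for index pairs under the
        given association matrix values.

        With ``mask=True`` (the leakage-safe default) association-derived
        features are computed on *pair-conditional views*: for pair (i, j)
        the circRNA-side features come from A with disease j's column
        zeroed, and the disease-side features from A with circRNA i's row
        zeroed. No feature can then encode the pair's own association, and
        every pair — known or unknown — is featurized by the same deletion
        operation, so the two classes stay exchangeable in the absence of
        real signal. With ``mask=False`` all features are taken verbatim
        from the full matrix (the optimistic variant).
        """
        A_values = np.asarray(A_values, dtype=float)
        if A_values.shape != (len(self.circ_ids), len(self.disease_ids)):
            raise ValueError("association matrix shape mismatch")
        pairs = np.asarray(pairs, dtype=int)
        ci, dj = pairs[:, 0], pairs[:, 1]
        if not mask:
            f1c, f2c, f1d, f2d, f4 = self._assoc_side_arrays(A_values)
            x = np.hstack(
                [
                    f1c[ci], f1d[dj], f2c[ci], f2d[dj], self._f3[ci],
                    f4.u[ci], f4.v[dj],
                    f4.deg_c[ci, None], f4.deg_d[dj, None],
                    f4.cent_c[ci], f4.cent_d[dj],
                ]
            )
        else:
            n = len(pairs)
            w_f1 = 2 + self.cfg.n_bins
            w_f2 = 1 + self.cfg.top_n + 2 * w_f1 + 3
            rank = (self.block_index["F4_pair"].stop
                    - self.block_index["F4_pair"].start - 8) // 2
            xc = np.empty((n, w_f1 + w_f2 + rank + 1 + 3))   # circ-side A-features
            xd = np.empty((n, w_f1 + w_f2 + rank + 1 + 3))   # disease-side
            for j in np.unique(dj):
                view = A_values.copy()
                view[:, j] = 0.0
                f1c, f2c, _, _, f4 = self._assoc_side_arrays(view)
                rows = np.nonzero(dj == j)[0]
                c = ci[rows]
                xc[rows] = np.hstack(
                    [f1c[c], f2c[c], f4.u[c], f4.deg_c[c, None], f4.cent_c[c]]
                )
            for i in np.unique(ci):
                view = A_values.copy()
                view[i, :] = 0.0
                _, _, f1d, f2d, f4 = self._assoc_side_arrays(view)
                rows = np.nonzero(ci == i)[0]
                d = dj[rows]
                xd[rows] = np.hstack(
                    [f1d[d], f2d[d], f4.v[d], f4.deg_d[d, None], f4.cent_d[d]]
                )
            x = np.hstack(
                [
                    xc[:, :w_f1], xd[:, :w_f1],
                    xc[:, w_f1 : w_f1 + w_f2], xd[:, w_f1 : w_f1 + w_f2],
                    self._f3[ci],
                    xc[:, w_f1 + w_f2 : w_f1 + w_f2 + rank],
                    xd[:, w_f1 + w_f2 : w_f1 + w_f2 + rank],
                    xc[:, -4:-3], xd[:, -4:-3],
                    xc[:, -3:], xd[:, -3:],
                ]
            )
        if not np.isfinite(x).all():
            raise ValueError("non-finite feature values produced")
        return x

    def all_pairs(self) -> np.ndarray:
        """Every (circ, disease) index pair in row-major order."""
        n_c, n_d = len(self.circ_ids), len(self.disease_ids)
        return np.array([(i, j) for i in range(n_c) for j in range(n_d)])


# ---------------------------------------------------------------------------
# PCA reduction
# ---------------------------------------------------------------------------


@dataclass
class PCAProjection:
    """Standardize-then-PCA projection fitted on training pairs only."""

    mean: np.ndarray
    scale: np.ndarray
    components: np.ndarray          # (n_components, n_features)
    explained_variance_ratio: np.ndarray
    pca_mean: np.ndarray = field(default=None)  # type: ignore[assignment]

    def transform(self, X: np.ndarray) -> np.ndarray:
        z = (np.asarray(X, dtype=float) - self.mean) / self.scale
        return (z - self.pca_mean) @ self.components.T

    def inverse_transform(self, Z: np.ndarray) -> np.ndarray:
        z = np.asarray(Z, dtype=float) @ self.components + self.pca_mean
        return z * self.scale + self.mean

    def to_json(self) -> dict:
        return {
            "mean": self.mean.tolist(),
            "scale": self.scale.tolist(),
            "components": self.components.tolist(),
            "explained_variance_ratio": self.explained_variance_ratio.tolist(),
            "pca_mean": self.pca_mean.tolist(),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "PCAProjection":
        return cls(
            np.asarray(obj["mean"]),
            np.asarray(obj["scale"]),
            np.asarray(obj["components"]),
            np.asarray(obj["explained_variance_ratio"]),
            np.asarray(obj["pca_mean"]),
        )


def pca_reduce(
    X: np.ndarray, cfg: FeatureConfig | None = None
) -> tuple[np.ndarray, PCAProjection]:
    """Fit a standardized PCA on training vectors and return the reduced
    matrix with the fitted projection (reapply verbatim to test vectors).

    ``cfg.pca_variance`` is a retained-variance fraction in (0, 1), an
    integer component count, or 1.0 for all components. Features are
    z-scored first (zero-variance features get unit scale) because the raw
    blocks mix scales from integer counts to unit-sum frequencies.
    """
    cfg = cfg or FeatureConfig()
    X = np.asarray(X, dtype=float)
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    z = (X - mean) / scale
    pv = cfg.pca_variance
    if isinstance(pv, float) and pv == 1.0:
        n_components = None
    elif isinstance(pv, float) and pv < 1.0:
        n_components = pv
    else:
        n_components = int(pv)
    pca = PCA(n_components=n_components, svd_solver="full")
    reduced = pca.fit_transform(z)
    proj = PCAProjection(
        mean, scale, pca.components_, pca.explained_variance_ratio_, pca.mean_
    )
    return reduced, proj
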