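"""Gradient-boosted regression trees, written from first principles.

Squared-error loss L(y, F) = (y - F)^2 / 2. The model starts from the
loss-minimizing constant F0 = mean(y) and at each stage fits a depth- and
leaf-size-limited regression tree to the negative gradient of the loss —
for squared error, simply the residuals y - F_{m-1}(x) — on a per-stage
row subsample. The line-search step for each terminal region has the
closed form "mean residual in the leaf", folded into the leaf values, and
the model advances by F_m = F_{m-1} + learning_rate * h_m.

Splits minimize the weighted child variance (equivalently maximize the
sum-of-squares reduction) over midpoints between consecutive sorted unique
values of ``max_features`` features sampled without replacement per node.
Ties break toward the lowest feature index, then the lowest threshold, so
fitting is bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger("circboost")

__all__ = ["GBDTParams", "RegressionTree", "GBDTModel", "fit", "predict"]

_GAIN_EPS = 1e-12


@dataclass(frozen=True)
class GBDTParams:
    """Hyperparameters; defaults are the tuned values used throughout."""

    n_estimators: int = 60
    learning_rate: float = 0.1
    max_depth: int = 9
    min_samples_split: int = 24
    min_samples_leaf: int = 11
    max_features: int | None = 9   # None: use all features
    subsample: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must lie in (0, 1]")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if self.min_samples_split < 2:
            raise ValueError("min_samples_split must be >= 2")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")
        if self.max_features is not None and self.max_features < 1:
            raise ValueError("max_features must be >= 1")
        if not 0 < self.subsample <= 1:
            raise ValueError("subsample must lie in (0, 1]")


@dataclass
class RegressionTree:
    """Flat-array binary regression tree.

    ``feature[n] == -1`` marks node *n* as a leaf carrying ``value[n]``;
    internal nodes route rows with x[feature] <= threshold to ``left``.
    """

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        out = np.empty(X.shape[0])
        stack = [(0, np.arange(X.shape[0]))]
        while stack:
            node, idx = stack.pop()
            if idx.size == 0:
                continue
            f = self.feature[node]
            if f < 0:
                out[idx] = self.value[node]
            else:
                go_left = X[idx, f] <= self.threshold[node]
                stack.append((self.left[node], idx[go_left]))
                stack.append((self.right[node], idx[~go_left]))
        return out

    @property
    def n_leaves(self) -> int:
        return int((self.feature < 0).sum())

    def to_json(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "value": self.value.tolist(),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "RegressionTree":
        return cls(
            np.asarray(obj["feature"], dtype=int),
            np.asarray(obj["threshold"], dtype=float),
            np.asarray(obj["left"], dtype=int),
            np.asarray(obj["right"], dtype=int),
            np.asarray(obj["value"], dtype=float),
        )


def _best_split(
    X: np.ndarray,
    r: np.ndarray,
    idx: np.ndarray,
    feats: np.ndarray,
    min_leaf: int,
) -> tuple[int, float] | None:
    """Best (feature, threshold) by sum-of-squares reduction, or None.

    Candidate thresholds are midpoints between consecutive sorted unique
    feature values. Ties break to the lowest feature index (features are
    scanned in ascending order with a strictly-greater acceptance) and,
    within a feature, the lowest threshold (first argmax in ascending
    threshold order).
    """
    n = idx.size
    rsub = r[idx]
    total = rsub.sum()
    parent_score = total * total / n
    best: tuple[int, float] | None = None
    best_score = parent_score + _GAIN_EPS
    for f in feats:
        x = X[idx, f]
        order = np.argsort(x, kind="stable")
        xs = x[order]
        cum = np.cumsum(rsub[order])
        nl = np.arange(1, n)
        valid = (xs[:-1] < xs[1:]) & (nl >= min_leaf) & (n - nl >= min_leaf)
        if not valid.any():
            continue
        left_sum = cum[:-1]
        score = np.full(n - 1, -np.inf)
        score[valid] = (
            left_sum[valid] ** 2 / nl[valid]
            + (total - left_sum[valid]) ** 2 / (n - nl[valid])
        )
        k = int(np.argmax(score))
        if score[k] > best_score:
            best_score = score[k]
            thr = (xs[k] + xs[k + 1]) / 2.0
            if thr >= xs[k + 1]:  # adjacent floats: midpoint rounded up
                thr = xs[k]
            best = (int(f), float(thr))
    return best


def _build_tree(
    X: np.ndarray, r: np.ndarray, idx: np.ndarray, params: GBDTParams, rng: np.random.Generator
) -> RegressionTree:
    n_features = X.shape[1]
    mf = n_features if params.max_features is None else min(params.max_features, n_features)
    feature: list[int] = []
    threshold: list[float] = []
    left: list[int] = []
    right: list[int] = []
    value: list[float] = []

    def new_node() -> int:
        feature.append(-1)
        threshold.append(0.0)
        left.append(-1)
        right.append(-1)
        value.append(0.0)
        return len(feature) - 1

    root = new_node()
    stack: list[tuple[int, np.ndarray, int]] = [(root, idx, 0)]
    while stack:
        node, rows, depth = stack.pop()
        rsub = r[rows]
        if (
            depth >= params.max_depth
            or rows.size < params.min_samples_split
            or rows.size < 2 * params.min_samples_leaf
            or np.ptp(rsub) == 0.0
        ):
            value[node] = float(rsub.mean())
            continue
        feats = np.sort(rng.choice(n_features, size=mf, replace=False))
        split = _best_split(X, r, rows, feats, params.min_samples_leaf)
        if split is None:
            value[node] = float(rsub.mean())
            continue
        f, thr = split
        go_left = X[rows, f] <= thr
        if not go_left.any() or go_left.all():
            value[node] = float(rsub.mean())
            continue
        feature[node] = f
        threshold[node] = thr
        nl = new_node()
        nr = new_node()
        left[node] = nl
        right[node] = nr
        # push right first so the left branch is processed next (DFS order
        # fixed => deterministic per-node feature sampling)
        stack.append((nr, rows[~go_left], depth + 1))
        stack.append((nl, rows[go_left], depth + 1))
    return RegressionTree(
        np.asarray(feature, dtype=int),
        np.asarray(threshold, dtype=float),
        np.asarray(left, dtype=int),
        np.asarray(right, dtype=int),
        np.asarray(value, dtype=float),
    )


@dataclass
class GBDTModel:
    """Additive model F(x) = F0 + learning_rate * sum_i tree_i(x)."""

    f0: float
    learning_rate: float
    n_features: int
    trees: list[RegressionTree] = field(default_factory=list)
    params: GBDTParams | None = None

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.n_features:
            raise ValueError(
                f"feature count mismatch: model expects {self.n_features}, got "
                f"{X.shape[1] if X.ndim == 2 else X.shape}"
            )
        out = np.full(X.shape[0], self.f0)
        for tree in self.trees:
            out += self.learning_rate * tree.predict(X)
        return out

    def staged_predict(self, X: np.ndarray):
        """Yield predictions after each boosting stage (stage 0 = F0)."""
        X = np.asarray(X, dtype=float)
        out = np.full(X.shape[0], self.f0)
        yield out.copy()
        for tree in self.trees:
            out += self.learning_rate * tree.predict(X)
            yield out.copy()

    def to_json(self) -> dict:
        return {
            "f0": self.f0,
            "learning_rate": self.learning_rate,
            "n_features": self.n_features,
            "trees": [t.to_json() for t in self.trees],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "GBDTModel":
        return cls(
            float(obj["f0"]),
            float(obj["learning_rate"]),
            int(obj["n_features"]),
            [RegressionTree.from_json(t) for t in obj["trees"]],
        )


def fit(X: np.ndarray, y: np.ndarray, params: GBDTParams | None = None) -> GBDTModel:
    """Train a boosted ensemble on features ``X`` and real-valued labels ``y``."""
    params = params or GBDTParams()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if y.shape != (X.shape[0],):
        raise ValueError("y length must match X rows")
    if not np.isfinite(X).all():
        raise ValueError("non-finite feature values")
    if not np.isfinite(y).all():
        raise ValueError("non-finite labels")
    n = X.shape[0]
    model = GBDTModel(float(y.mean()), params.learning_rate, X.shape[1], params=params)
    if params.min_samples_split > n:
        logger.warning(
            "min_samples_split=%d exceeds n=%d; returning the constant model",
            params.min_samples_split, n,
        )
        return model
    rng = np.random.default_rng(params.seed)
    pred = np.full(n, model.f0)
    n_sub = max(1, int(round(params.subsample * n)))
    for _ in range(params.n_estimators):
        residual = y - pred
        if np.abs(residual).max() == 0.0:
            break
        rows = (
            np.sort(rng.choice(n, size=n_sub, replace=False))
            if params.subsample < 1.0
            else np.arange(n)
        )
        tree = _build_tree(X, residual, rows, params, rng)
        model.trees.append(tree)
        pred += params.learning_rate * tree.predict(X)
    return model


def predict(model: GBDTModel, X: np.ndarray) -> np.ndarray:
    """Score rows of ``X`` with a fitted model."""
    return model.predict(X)


def feature_importances(model: GBDTModel) -> np.ndarray:
    """Split-count importances (convenience diagnostic, not part of the
    modeled method): fraction of splits using each feature."""
    counts = np.zeros(model.n_features)
    for tree in model.trees:
        for f in tree.feature:
            if f >= 0:
                counts[f] += 1
    total = counts.sum()
    return counts / total if total > 0 else counts
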