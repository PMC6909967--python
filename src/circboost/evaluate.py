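"""Balanced leave-one-out cross-validation and ranking metrics.

The protocol: all known associations are positives; an equal number of
negatives is drawn uniformly without replacement from the unknown cells,
once per run from the given seed. For every sample in the balanced set the
model is retrained from scratch on the remaining samples — with the
held-out association zeroed in the association matrix before any
association-derived feature is computed, so the held-out label never leaks
into its own feature vector — and the held-out sample is scored. Held-out
scores sorted in descending order provide the thresholds of the ROC curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from . import gbdt
from .features import FeatureConfig, PairFeatureAssembler, pca_reduce
from .io import AssociationMatrix

logger = logging.getLogger("circboost")

__all__ = ["EvalReport", "roc_auc", "prf", "topk_hits", "balanced_loocv"]


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """ROC curve and area from a descending-threshold sweep.

    Every distinct score is used as a threshold; tied scores advance the
    curve diagonally, so the trapezoidal area equals the Mann-Whitney
    statistic (#{pos > neg} + 1/2 #{ties}) / (n_pos * n_neg).

    Returns (auc, points) where points is an (m, 2) array of (FPR, TPR)
    starting at (0, 0) and ending at (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs at least one positive and one negative")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    points = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and sorted_scores[j] == sorted_scores[i]:
            j += 1
        tp += int(sorted_labels[i:j].sum())
        fp += (j - i) - int(sorted_labels[i:j].sum())
        points.append((fp / n_neg, tp / n_pos))
        i = j
    pts = np.array(points)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return auc, pts


def prf(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> dict[str, float]:
    """Precision, recall, and F-measure at ``score >= threshold``.

    An empty predicted-positive set makes precision undefined; it is
    reported as 0 together with ``"degenerate": True``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=float)
    pred = scores >= threshold
    tp = int((pred & (labels == 1)).sum())
    fp = int((pred & (labels == 0)).sum())
    fn = int((~pred & (labels == 1)).sum())
    degenerate = (tp + fp) == 0
    precision = tp / (tp + fp) if not degenerate else 0.0
    recall = tp / (tp + fn) if (tp + fn) > 0 else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return {
        "precision": precision,
        "recall": recall,
        "f_measure": f,
        "threshold": float(threshold),
        "degenerate": bool(degenerate),
    }


def best_f_threshold(scores: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """The observed score threshold maximizing the F-measure."""
    best = {"f_measure": -1.0}
    for t in sorted(set(np.asarray(scores, dtype=float))):
        cur = prf(scores, labels, threshold=t)
        if cur["f_measure"] > best["f_measure"]:
            best = cur
    return best


def topk_hits(
    scores: np.ndarray, is_known: np.ndarray, ks: list[int]
) -> dict[int, int]:
    """Known associations recovered among the k highest-scoring pairs."""
    scores = np.asarray(scores, dtype=float)
    is_known = np.asarray(is_known, dtype=bool)
    order = np.argsort(-scores, kind="stable")
    ranked_known = is_known[order]
    cum = np.cumsum(ranked_known)
    out = {}
    for k in ks:
        kk = min(int(k), len(scores))
        out[int(k)] = int(cum[kk - 1]) if kk > 0 else 0
    return out


# ---------------------------------------------------------------------------
# Balanced LOOCV
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    """Outcome of one balanced-LOOCV run."""

    scores: np.ndarray
    labels: np.ndarray
    fold_pairs: list[tuple[str, str]]
    auc: float
    roc_points: np.ndarray
    precision: float
    recall: float
    f_measure: float
    threshold: float
    best_f: dict[str, float]
    seed: int
    masked: bool
    scaled_down: bool
    n_positives: int
    n_folds: int
    topk: dict[int, int] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "auc": self.auc,
            "precision": self.precision,
            "recall": self.recall,
            "f_measure": self.f_measure,
            "threshold": self.threshold,
            "best_f": self.best_f,
            "seed": self.seed,
            "masked": self.masked,
            "scaled_down": self.scaled_down,
            "n_positives": self.n_positives,
            "n_folds": self.n_folds,
            "scores": self.scores.tolist(),
            "labels": self.labels.tolist(),
            "fold_pairs": [list(p) for p in self.fold_pairs],
            "roc_points": self.roc_points.tolist(),
            "topk": {str(k): v for k, v in self.topk.items()},
        }


def _balanced_samples(
    A: AssociationMatrix, rng: np.random.Generator, disease: str | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """All positive cells plus an equal-size uniform draw of negative cells."""
    values = A.values
    if disease is not None:
        j = A.disease_ids.index(disease)
        col_mask = np.zeros_like(values, dtype=bool)
        col_mask[:, j] = True
        pos = np.argwhere((values == 1) & col_mask)
        neg_pool = np.argwhere((values == 0) & col_mask)
    else:
        pos = np.argwhere(values == 1)
        neg_pool = np.argwhere(values == 0)
    if len(pos) < 2:
        raise ValueError("need at least 2 known associations")
    if len(neg_pool) < len(pos):
        raise ValueError("fewer unknown cells than known associations")
    chosen = rng.choice(len(neg_pool), size=len(pos), replace=False)
    samples = np.vstack([pos, neg_pool[np.sort(chosen)]])
    labels = np.concatenate([np.ones(len(pos)), np.zeros(len(pos))])
    return samples, labels


def balanced_loocv(
    A: AssociationMatrix,
    assembler: PairFeatureAssembler,
    model_params: gbdt.GBDTParams | None = None,
    seed: int = 0,
    n_folds: int | None = None,
    mask: bool = True,
    use_pca: bool = False,
    feature_cfg: FeatureConfig | None = None,
    threshold: float = 0.5,
    disease: str | None = None,
    shuffle_labels: bool = False,
) -> EvalReport:
    """Balanced leave-one-out cross-validation of the full pipeline.

    Parameters
    ----------
    n_folds:
        If given, only this many of the balanced samples (drawn without
        replacement) are held out and scored; the report's ``scaled_down``
        flag records the reduction. Training always uses all remaining
        balanced samples.
    mask:
        Use pair-conditional feature views (the default, leakage-safe
        protocol): each sample's circRNA-side association features are
        computed with its disease's column zeroed and vice versa, so no
        feature vector encodes its own label, for training and held-out
        samples alike. ``mask=False`` computes all features from the full
        matrix, reproducing the optimistic variant.
    shuffle_labels:
        Permute the balanced labels once before training (permutation
        null); scores are then evaluated against the permuted labels.
    """
    model_params = model_params or gbdt.GBDTParams()
    feature_cfg = feature_cfg or assembler.cfg
    rng = np.random.default_rng(seed)
    samples, labels = _balanced_samples(A, rng, disease=disease)
    if shuffle_labels:
        # permutation null: break the sample/label pairing
        labels = labels[rng.permutation(len(labels))]
    n_samples = len(samples)
    if n_folds is not None and n_folds < n_samples:
        fold_ids = np.sort(rng.choice(n_samples, size=n_folds, replace=False))
        scaled_down = True
    else:
        fold_ids = np.arange(n_samples)
        scaled_down = False

    x = assembler.feature_matrix(samples, A.values, mask=mask)
    held_scores = np.empty(len(fold_ids))
    held_labels = labels[fold_ids]
    for out_pos, f in enumerate(fold_ids):
        train = np.delete(np.arange(n_samples), f)
        x_tr, y_tr = x[train], labels[train]
        x_te = x[f : f + 1]
        if use_pca:
            x_tr, proj = pca_reduce(x_tr, feature_cfg)
            x_te = proj.transform(x_te)
        fold_seed = (seed * 1_000_003 + int(f)) % (2**31 - 1)
        model = gbdt.fit(x_tr, y_tr, replace(model_params, seed=fold_seed))
        held_scores[out_pos] = model.predict(x_te)[0]

    auc, pts = roc_auc(held_scores, held_labels)
    p = prf(held_scores, held_labels, threshold=threshold)
    fold_pairs = [
        (assembler.circ_ids[samples[f][0]], assembler.disease_ids[samples[f][1]])
        for f in fold_ids
    ]
    return EvalReport(
        scores=held_scores,
        labels=held_labels,
        fold_pairs=fold_pairs,
        auc=auc,
        roc_points=pts,
        precision=p["precision"],
        recall=p["recall"],
        f_measure=p["f_measure"],
        threshold=threshold,
        best_f=best_f_threshold(held_scores, held_labels),
        seed=seed,
        masked=mask,
        scaled_down=scaled_down,
        n_positives=int(labels.sum()),
        n_folds=len(fold_ids),
    )


def score_all_pairs(
    A: AssociationMatrix,
    assembler: PairFeatureAssembler,
    model_params: gbdt.GBDTParams | None = None,
    seed: int = 0,
    mask: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Train on the balanced set and score every (circRNA, disease) cell.

    Returns (scores, is_known) flattened in row-major pair order. With
    the default pair-view masking a known pair's rank reflects the rest of
    the network, never its own label.
    """
    model_params = model_params or gbdt.GBDTParams()
    rng = np.random.default_rng(seed)
    samples, labels = _balanced_samples(A, rng)
    x_tr = assembler.feature_matrix(samples, A.values, mask=mask)
    model = gbdt.fit(x_tr, labels, model_params)
    all_pairs = assembler.all_pairs()
    is_known = A.values[all_pairs[:, 0], all_pairs[:, 1]] == 1
    scores = model.predict(assembler.feature_matrix(all_pairs, A.values, mask=mask))
    return scores, is_known
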