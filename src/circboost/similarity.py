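"""circRNA and disease similarity matrices.

Three circRNA views — global-alignment sequence similarity, information-
content GO-annotation similarity, and expression-profile Pearson similarity —
and two disease views — gene-set Jaccard similarity and Wang-method ontology
semantic similarity — plus the weighted integration of the disease views.

Every function returns a :class:`~circboost.io.SimilarityMatrix` that is
symmetric, has unit diagonal, and lies in [0, 1]. Entities missing a data
source receive a *neutral* row (0 off-diagonal, 1 diagonal) so that no
entity is ever dropped from the pipeline.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from Bio import Align

from .io import ExpressionMatrix, OntologyDAG, SimilarityMatrix

logger = logging.getLogger("circboost")

__all__ = [
    "AlignmentParams",
    "DiseaseSimWeights",
    "sequence_similarity",
    "go_semantic_similarity",
    "expression_similarity",
    "disease_functional_similarity",
    "disease_semantic_similarity",
    "integrate_disease",
    "neutralize_missing",
]


@dataclass(frozen=True)
class AlignmentParams:
    """Needleman-Wunsch scoring. Gap penalties are stored as magnitudes;
    a gap of length L costs ``gap_open + gap_extend * L`` (subtracted from
    the score)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = 2.0
    gap_extend: float = 0.5

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties are magnitudes and must be >= 0")


@dataclass(frozen=True)
class DiseaseSimWeights:
    """Mixing weight for disease functional vs semantic similarity."""

    alpha: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


def _finalize(ids: list[str], values: np.ndarray) -> SimilarityMatrix:
    values = np.clip(values, 0.0, 1.0)
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return SimilarityMatrix(list(ids), values).validate()


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.mode = "global"
    al.match_score = params.match
    al.mismatch_score = params.mismatch
    al.open_gap_score = -(params.gap_open + params.gap_extend)
    al.extend_gap_score = -params.gap_extend
    return al


def nw_score(a: str, b: str, params: AlignmentParams | None = None) -> float:
    """Global affine-gap alignment score of two sequences."""
    params = params or AlignmentParams()
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    return float(_aligner(params).score(a, b))


def sequence_similarity(
    seqs: dict[str, str], params: AlignmentParams | None = None
) -> SimilarityMatrix:
    """Pairwise global-alignment similarity (Seq_CS).

    The raw alignment score is normalized by the larger of the two
    self-alignment scores and clamped to [0, 1], guaranteeing a unit
    diagonal and boundedness.
    """
    params = params or AlignmentParams()
    ids = sorted(seqs)
    if len(ids) < 2:
        raise ValueError("need at least 2 sequences")
    for name in ids:
        if not seqs[name]:
            raise ValueError(f"empty sequence for {name!r}")
    al = _aligner(params)
    n = len(ids)
    self_scores = np.array([al.score(seqs[c], seqs[c]) for c in ids])
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            raw = al.score(seqs[ids[i]], seqs[ids[j]])
            denom = max(self_scores[i], self_scores[j])
            values[i, j] = values[j, i] = raw / denom if denom > 0 else 0.0
    return _finalize(ids, values)


def go_semantic_similarity(
    annot: dict[str, set[str]], universe_size: int, ids: list[str] | None = None
) -> SimilarityMatrix:
    """Information-content similarity of GO annotation sets (Fun_CS).

    With P(X) = |terms(X)| / universe and P(i,j) = |terms(i) & terms(j)| /
    universe, sim(i,j) = 2 ln P(i,j) / (ln P(i) + ln P(j)) for a non-empty
    intersection, else 0; clamped to [0, 1]; self-similarity is 1.
    Entities without annotations get a neutral row.
    """
    ids = sorted(annot) if ids is None else list(ids)
    union: set[str] = set()
    for c in ids:
        union |= annot.get(c, set())
    if universe_size < len(union):
        raise ValueError(
            f"universe_size {universe_size} smaller than annotation union {len(union)}"
        )
    n = len(ids)
    values = np.eye(n)
    sets = [annot.get(c, set()) for c in ids]
    for i in range(n):
        if not sets[i]:
            logger.warning("no GO annotations for %r; neutral similarity row", ids[i])
    log_p = [
        math.log(len(s) / universe_size) if s else 0.0 for s in sets
    ]
    for i in range(n):
        for j in range(i + 1, n):
            inter = sets[i] & sets[j]
            if not inter:
                continue
            denom = log_p[i] + log_p[j]
            if denom == 0.0:  # both sets cover the whole universe
                values[i, j] = values[j, i] = 1.0
                continue
            sim = 2.0 * math.log(len(inter) / universe_size) / denom
            values[i, j] = values[j, i] = sim
    return _finalize(ids, values)


def expression_similarity(expr: ExpressionMatrix) -> SimilarityMatrix:
    """Pearson-correlation similarity of expression profiles (ES).

    Negative correlations clamp to 0 so that "anti-correlated" means
    "not similar" and downstream fusion weights stay non-negative.
    Constant rows get a neutral similarity row.
    """
    if len(expr.site_labels) < 2:
        raise ValueError("need >= 2 expression sites")
    x = expr.values
    sd = x.std(axis=1)
    constant = sd == 0.0
    for k in np.nonzero(constant)[0]:
        logger.warning(
            "constant expression profile for %r; neutral similarity row",
            expr.circ_ids[k],
        )
    safe = x.copy()
    # give constant rows a dummy non-constant profile, then zero them out below
    safe[constant] = np.arange(x.shape[1])
    corr = np.corrcoef(safe)
    corr[constant, :] = 0.0
    corr[:, constant] = 0.0
    return _finalize(list(expr.circ_ids), corr)


def disease_functional_similarity(genes: dict[str, set[str]]) -> SimilarityMatrix:
    """Jaccard similarity of disease gene sets (DFS)."""
    ids = sorted(genes)
    n = len(ids)
    sets = [genes.get(d, set()) for d in ids]
    for i in range(n):
        if not sets[i]:
            logger.warning("no genes for disease %r; neutral similarity row", ids[i])
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            if not sets[i] or not sets[j]:
                continue
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            values[i, j] = values[j, i] = inter / union
    return _finalize(ids, values)


def _wang_s_values(dag: OntologyDAG, term: str, w: float) -> dict[str, float]:
    """Semantic contribution S of *term* and each of its ancestors.

    S(term) = 1; walking up is_a edges, S(parent) = max over its children on
    the ancestor closure of w * S(child).
    """
    g = dag.graph()
    if term not in dag.terms:
        raise KeyError(f"disease term {term!r} not found in ontology")
    s = {term: 1.0}
    frontier = [term]
    while frontier:
        nxt = []
        for t in frontier:
            for parent in g.successors(t):
                cand = w * s[t]
                if cand > s.get(parent, 0.0):
                    s[parent] = cand
                    nxt.append(parent)
        frontier = nxt
    return s


def disease_semantic_similarity(
    dag: OntologyDAG, disease_terms: dict[str, str], w: float = 0.8
) -> SimilarityMatrix:
    """Wang-method ontology semantic similarity of diseases (DSS).

    sim(A, B) = sum over shared ancestor terms of (S_A(t) + S_B(t)) divided
    by (sum S_A + sum S_B), with contribution decay *w* per is_a edge.
    """
    ids = sorted(disease_terms)
    svals = {d: _wang_s_values(dag, disease_terms[d], w) for d in ids}
    totals = {d: sum(svals[d].values()) for d in ids}
    n = len(ids)
    values = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            si, sj = svals[ids[i]], svals[ids[j]]
            shared = set(si) & set(sj)
            if not shared:
                continue
            num = sum(si[t] + sj[t] for t in shared)
            values[i, j] = values[j, i] = num / (totals[ids[i]] + totals[ids[j]])
    return _finalize(ids, values)


def integrate_disease(
    dfs: SimilarityMatrix, dss: SimilarityMatrix, w: DiseaseSimWeights | None = None
) -> SimilarityMatrix:
    """DS = alpha * DFS + (1 - alpha) * DSS."""
    w = w or DiseaseSimWeights()
    if dfs.ids != dss.ids:
        raise ValueError("disease orderings differ between DFS and DSS")
    values = w.alpha * dfs.values + (1.0 - w.alpha) * dss.values
    return _finalize(list(dfs.ids), values)


def neutralize_missing(
    sim: SimilarityMatrix, all_ids: list[str]
) -> SimilarityMatrix:
    """Expand *sim* to cover *all_ids*, giving absent entities a neutral row
    (0 off-diagonal, 1 diagonal) so other data views dominate for them."""
    pos = {x: k for k, x in enumerate(sim.ids)}
    order = sorted(all_ids)
    n = len(order)
    values = np.eye(n)
    idx = [pos.get(x) for x in order]
    for a in range(n):
        if idx[a] is None:
            logger.warning("entity %r missing from a similarity source; neutral row", order[a])
            continue
        for b in range(n):
            if b != a and idx[b] is not None:
                values[a, b] = sim.values[idx[a], idx[b]]
    return _finalize(order, values)
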