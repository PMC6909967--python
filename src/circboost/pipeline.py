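"""End-to-end orchestration: raw inputs -> fused similarities -> features.

The supervised universe is the set of entities appearing in the
association edge list; similarity matrices are computed over (or expanded
to) exactly those entities, with neutral rows for entities missing a data
source.
"""

from __future__ import annotations

import logging

import numpy as np

from . import similarity as sim
from . import snf
from .features import FeatureConfig, PairFeatureAssembler
from .io import AssociationMatrix, ExpressionMatrix, SimilarityMatrix
from .synthetic import SyntheticBundle

logger = logging.getLogger("circboost")

__all__ = ["restrict_to_known", "fused_circ_similarity", "disease_similarity",
           "build_assembler"]


def restrict_to_known(A: AssociationMatrix) -> AssociationMatrix:
    """Drop circRNAs/diseases with no known association (they cannot be
    positives and have no supervision signal)."""
    keep_c = A.values.sum(axis=1) > 0
    keep_d = A.values.sum(axis=0) > 0
    if keep_c.all() and keep_d.all():
        return A
    n_drop = int((~keep_c).sum() + (~keep_d).sum())
    logger.info("dropping %d entity(ies) without associations", n_drop)
    return AssociationMatrix(
        [c for c, k in zip(A.circ_ids, keep_c) if k],
        [d for d, k in zip(A.disease_ids, keep_d) if k],
        A.values[np.ix_(keep_c, keep_d)],
    )


def fused_circ_similarity(
    circ_ids: list[str],
    seqs: dict[str, str],
    go_annotations: dict[str, set[str]],
    go_universe_size: int,
    expression: ExpressionMatrix,
    align_params: sim.AlignmentParams | None = None,
    snf_params: snf.SNFParams | None = None,
) -> SimilarityMatrix:
    """Sequence + GO + expression views fused by SNF over *circ_ids*."""
    circ_ids = sorted(circ_ids)
    seq_subset = {c: seqs[c] for c in circ_ids if c in seqs}
    seq_cs = sim.neutralize_missing(
        sim.sequence_similarity(seq_subset, align_params), circ_ids
    )
    fun_cs = sim.go_semantic_similarity(
        {c: go_annotations.get(c, set()) for c in circ_ids},
        go_universe_size,
        ids=circ_ids,
    )
    have_expr = [c for c in circ_ids if c in expression.circ_ids]
    pos = {c: k for k, c in enumerate(expression.circ_ids)}
    expr_subset = ExpressionMatrix(
        have_expr,
        list(expression.site_labels),
        expression.values[[pos[c] for c in have_expr]],
    )
    es = sim.neutralize_missing(sim.expression_similarity(expr_subset), circ_ids)
    return snf.fuse([seq_cs, fun_cs, es], snf_params)


def disease_similarity(
    disease_ids: list[str],
    disease_genes: dict[str, set[str]],
    ontology,
    disease_terms: dict[str, str],
    weights: sim.DiseaseSimWeights | None = None,
    precomputed_dss: SimilarityMatrix | None = None,
) -> SimilarityMatrix:
    """Jaccard gene-set + Wang ontology similarity, alpha-integrated."""
    disease_ids = sorted(disease_ids)
    dfs = sim.disease_functional_similarity(
        {d: disease_genes.get(d, set()) for d in disease_ids}
    )
    if precomputed_dss is not None:
        dss = precomputed_dss.subset(disease_ids)
    else:
        dss = sim.disease_semantic_similarity(
            ontology, {d: disease_terms[d] for d in disease_ids}
        )
    return sim.integrate_disease(dfs, dss, weights)


def build_assembler(
    bundle: SyntheticBundle,
    feature_cfg: FeatureConfig | None = None,
    align_params: sim.AlignmentParams | None = None,
    snf_params: snf.SNFParams | None = None,
    weights: sim.DiseaseSimWeights | None = None,
    restrict: bool = False,
) -> tuple[AssociationMatrix, PairFeatureAssembler]:
    """Full preprocessing of a synthetic bundle down to a feature assembler.

    By default the whole generated association matrix is kept, including
    entities without any known association: restricting the universe to
    associated entities (as an edge-list export inherently does) makes a
    held-out positive's masked feature row reachable only by positives —
    an inclusion bias that leaks the label. Pass ``restrict=True`` to
    reproduce the edge-list behaviour.
    """
    A = restrict_to_known(bundle.associations) if restrict else bundle.associations
    P = fused_circ_similarity(
        A.circ_ids,
        bundle.seqs,
        bundle.go_annotations,
        bundle.go_universe_size,
        bundle.expression,
        align_params=align_params,
        snf_params=snf_params,
    )
    DS = disease_similarity(
        A.disease_ids,
        bundle.disease_genes,
        bundle.ontology,
        bundle.disease_terms,
        weights=weights,
    )
    assembler = PairFeatureAssembler(P, DS, bundle.seqs, feature_cfg)
    return A, assembler
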