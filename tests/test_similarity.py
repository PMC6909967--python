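import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from circboost import similarity as sim
from circboost.io import ExpressionMatrix, OntologyDAG, SimilarityMatrix

from oracles import nw_affine_score, pearson_two_pass


def _check_contract(m: SimilarityMatrix):
    m.validate()


class TestSequenceSimilarity:
    def test_identical_sequences_have_unit_similarity(self):
        m = sim.sequence_similarity({"a": "ACGTACGT", "b": "ACGTACGT"})
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_self_alignment_score(self):
        # perfect match: raw score = length * match
        assert sim.nw_score("ACGT", "ACGT") == pytest.approx(4.0)

    def test_matches_exhaustive_affine_dp(self, rng):
        params = sim.AlignmentParams(match=1, mismatch=-1, gap_open=2, gap_extend=0.5)
        for _ in range(60):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 13)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(1, 13)))
            assert sim.nw_score(a, b, params) == pytest.approx(
                nw_affine_score(a, b, 1, -1, 2, 0.5), abs=1e-9
            )

    def test_permutation_equivariance(self, rng):
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=20)) for i in range(5)}
        m = sim.sequence_similarity(seqs)
        # identifiers are sorted internally, so any input ordering is identical
        m2 = sim.sequence_similarity(dict(reversed(list(seqs.items()))))
        assert m.ids == m2.ids
        assert np.allclose(m.values, m2.values)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sim.sequence_similarity({"a": "", "b": "ACGT"})


class TestGoSimilarity:
    def test_identical_sets(self):
        m = sim.go_semantic_similarity({"a": {"g1", "g2"}, "b": {"g1", "g2"}}, 100)
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_disjoint_sets(self):
        m = sim.go_semantic_similarity({"a": {"g1"}, "b": {"g2"}}, 100)
        assert m.values[0, 1] == 0.0

    def test_hand_evaluated_formula_clamps(self):
        # 2 ln(0.01) / (ln 0.02 + ln 0.02) = 1.177... -> clamped to 1
        raw = 2 * math.log(0.01) / (2 * math.log(0.02))
        assert raw == pytest.approx(1.1772, abs=1e-4)
        m = sim.go_semantic_similarity(
            {"a": {"g1", "g2"}, "b": {"g2", "g3"}}, 100
        )
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_universe_too_small_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            sim.go_semantic_similarity({"a": {"g1", "g2"}, "b": {"g3"}}, 2)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 6), st.integers(0, 6), st.integers(1, 6))
    def test_monotone_in_overlap(self, na, nb, extra):
        # adding a shared term never decreases similarity
        universe = 1000
        a = {f"a{i}" for i in range(na)} | {"shared0"}
        b = {f"b{i}" for i in range(nb)} | {"shared0"}
        before = sim.go_semantic_similarity({"x": a, "y": b}, universe).values[0, 1]
        a2 = a | {f"s{extra}"}
        b2 = b | {f"s{extra}"}
        after = sim.go_semantic_similarity({"x": a2, "y": b2}, universe).values[0, 1]
        assert after >= before - 1e-12


class TestExpressionSimilarity:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        expr = ExpressionMatrix(
            ["a", "b"], [f"s{i}" for i in range(10)], np.vstack([x, 2 * x + 3])
        )
        assert sim.expression_similarity(expr).values[0, 1] == pytest.approx(1.0)

    def test_anticorrelation_clamps_to_zero(self):
        x = np.arange(10.0)
        expr = ExpressionMatrix(
            ["a", "b"], [f"s{i}" for i in range(10)], np.vstack([x, -x])
        )
        assert sim.expression_similarity(expr).values[0, 1] == 0.0

    def test_matches_two_pass_pearson(self, rng):
        vals = rng.normal(size=(6, 10))
        expr = ExpressionMatrix(
            [f"c{i}" for i in range(6)], [f"s{i}" for i in range(10)], vals
        )
        m = sim.expression_similarity(expr)
        for i in range(6):
            for j in range(i + 1, 6):
                expected = max(0.0, pearson_two_pass(vals[i], vals[j]))
                assert m.values[i, j] == pytest.approx(expected, abs=1e-12)

    def test_single_site_rejected(self):
        with pytest.raises(ValueError):
            ExpressionMatrix(["a", "b"], ["s0"], np.ones((2, 1)))


class TestDiseaseSimilarity:
    def test_jaccard_examples(self):
        m = sim.disease_functional_similarity(
            {"x": {"a", "b"}, "y": {"b", "c"}, "z": {"d"}}
        )
        # x,y share 1 of 3; z disjoint from both
        assert m.values[0, 1] == pytest.approx(1 / 3)
        assert m.values[0, 2] == 0.0

    def test_identical_gene_sets(self):
        m = sim.disease_functional_similarity({"x": {"a"}, "y": {"a"}})
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_wang_two_leaves_under_root(self):
        dag = OntologyDAG({"root", "u", "v"}, [("u", "root"), ("v", "root")])
        m = sim.disease_semantic_similarity(dag, {"du": "u", "dv": "v"})
        # S-values {self: 1, root: 0.8}; sim = (0.8+0.8)/(1.8+1.8) = 4/9
        assert m.values[0, 1] == pytest.approx(4 / 9)

    def test_same_term_gives_unit(self):
        dag = OntologyDAG({"root", "u"}, [("u", "root")])
        m = sim.disease_semantic_similarity(dag, {"d1": "u", "d2": "u"})
        assert m.values[0, 1] == pytest.approx(1.0)

    def test_disjoint_forest_components(self):
        dag = OntologyDAG({"r1", "r2", "u", "v"}, [("u", "r1"), ("v", "r2")])
        m = sim.disease_semantic_similarity(dag, {"du": "u", "dv": "v"})
        assert m.values[0, 1] == 0.0

    def test_missing_term_named_in_error(self):
        dag = OntologyDAG({"root"}, [])
        with pytest.raises(KeyError, match="nope"):
            sim.disease_semantic_similarity(dag, {"d": "nope"})

    @pytest.mark.parametrize(
        "alpha,expected", [(1.0, 0.4), (0.0, 0.8), (0.5, 0.6)]
    )
    def test_integration_weights(self, alpha, expected):
        ids = ["x", "y"]
        dfs = SimilarityMatrix(ids, np.array([[1.0, 0.4], [0.4, 1.0]]))
        dss = SimilarityMatrix(ids, np.array([[1.0, 0.8], [0.8, 1.0]]))
        ds = sim.integrate_disease(dfs, dss, sim.DiseaseSimWeights(alpha))
        assert ds.values[0, 1] == pytest.approx(expected)

    def test_integration_dimension_mismatch(self):
        dfs = SimilarityMatrix(["x", "y"], np.eye(2))
        dss = SimilarityMatrix(["x", "z"], np.eye(2))
        with pytest.raises(ValueError):
            sim.integrate_disease(dfs, dss)


def test_all_similarity_outputs_satisfy_contract(rng):
    seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=30)) for i in range(4)}
    annot = {f"s{i}": {f"g{rng.integers(8)}" for _ in range(3)} or {"g0"} for i in range(4)}
    expr = ExpressionMatrix(
        [f"s{i}" for i in range(4)], [f"x{k}" for k in range(6)], rng.normal(size=(4, 6))
    )
    genes = {f"d{i}": {f"h{rng.integers(6)}" for _ in range(3)} or {"h0"} for i in range(3)}
    for m in [
        sim.sequence_similarity(seqs),
        sim.go_semantic_similarity(annot, 100),
        sim.expression_similarity(expr),
        sim.disease_functional_similarity(genes),
    ]:
        _check_contract(m)


def test_neutralize_missing_expands_with_neutral_rows():
    m = SimilarityMatrix(["a", "b"], np.array([[1.0, 0.5], [0.5, 1.0]]))
    out = sim.neutralize_missing(m, ["a", "b", "c"])
    assert out.ids == ["a", "b", "c"]
    assert out.values[0, 1] == pytest.approx(0.5)
    assert out.values[0, 2] == 0.0 and out.values[2, 2] == 1.0
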