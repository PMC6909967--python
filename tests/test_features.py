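import numpy as np
import pytest

from circboost import features as feat
from circboost.features import FeatureConfig, PairFeatureAssembler, pca_reduce
from circboost.io import AssociationMatrix, SimilarityMatrix

from oracles import betweenness_brute, closeness_brute, eigenvector_power


def _sim(rng, n, prefix):
    v = rng.random((n, n))
    v = (v + v.T) / 2
    np.fill_diagonal(v, 1.0)
    return SimilarityMatrix([f"{prefix}{i:02d}" for i in range(n)], v)


@pytest.fixture()
def tiny_setup(rng):
    n_c, n_d = 8, 5
    P = _sim(rng, n_c, "c")
    DS = _sim(rng, n_d, "d")
    seqs = {
        f"c{i:02d}": "".join(rng.choice(list("ACGT"), size=40)) for i in range(n_c)
    }
    A = (rng.random((n_c, n_d)) < 0.35).astype(float)
    A[0, 0] = 1.0  # ensure at least one association
    cfg = FeatureConfig(svd_rank=2)
    return P, DS, seqs, A, cfg


class TestF1:
    def test_degree_from_association_row(self, tiny_setup):
        P, DS, seqs, A, cfg = tiny_setup
        f1 = feat.f1_statistics(P, A.sum(axis=1), cfg)
        assert np.array_equal(f1[:, 0], A.sum(axis=1))

    def test_histogram_bin_convention(self):
        ids = ["a", "b", "c"]
        v = np.full((3, 3), 0.5)
        np.fill_diagonal(v, 1.0)
        m = SimilarityMatrix(ids, v)
        f1 = feat.f1_statistics(m, np.zeros(3), FeatureConfig())
        hist = f1[:, 2:]
        # all off-diagonal similarities are 0.5 -> mass in bin [0.5, 0.6)
        assert np.array_equal(hist[:, 5], np.full(3, 2.0))
        assert hist.sum() == pytest.approx(3 * 2)

    def test_histogram_counts_conserved(self, rng):
        m = _sim(rng, 9, "e")
        f1 = feat.f1_statistics(m, np.zeros(9), FeatureConfig())
        assert np.allclose(f1[:, 2:].sum(axis=1), 8.0)

    def test_last_bin_closed(self):
        ids = ["a", "b"]
        m = SimilarityMatrix(ids, np.array([[1.0, 1.0], [1.0, 1.0]]))
        f1 = feat.f1_statistics(m, np.zeros(2), FeatureConfig())
        assert f1[0, -1] == 1.0  # similarity 1.0 lands in the final bin


class TestCentralities:
    def test_path_graph_betweenness(self):
        adj = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], dtype=float)
        bc, cc, ec = feat.centralities_from_adjacency(adj)
        assert bc[1] == pytest.approx(1.0)
        assert bc[0] == bc[2] == 0.0

    def test_complete_graph_equal_eigenvector(self):
        adj = np.ones((5, 5)) - np.eye(5)
        _, _, ec = feat.centralities_from_adjacency(adj)
        assert np.allclose(ec, ec[0])

    def test_matches_bruteforce_on_random_graphs(self, rng):
        for _ in range(12):
            n = int(rng.integers(3, 9))
            adj = (rng.random((n, n)) < 0.45).astype(float)
            adj = np.triu(adj, 1)
            adj = adj + adj.T
            if not adj.any():
                continue
            evals = np.linalg.eigvalsh(adj)
            if evals[-1] - evals[-2] < 1e-6:
                continue  # degenerate principal eigenspace: centrality ill-defined
            bc, cc, ec = feat.centralities_from_adjacency(adj)
            assert np.allclose(bc, betweenness_brute(adj), atol=1e-9)
            assert np.allclose(cc, closeness_brute(adj), atol=1e-9)
            assert np.allclose(ec, eigenvector_power(adj), atol=1e-7)


class TestF3:
    def test_gc_content(self):
        out = feat.f3_sequence({"x": "ATGC"}, FeatureConfig(kmer_ks=(2,)))
        assert out[0, 0] == pytest.approx(0.5)

    def test_homopolymer_dimers(self):
        cfg = FeatureConfig(kmer_ks=(2,))
        out = feat.f3_sequence({"x": "AAAA"}, cfg)
        assert out[0, 1] == pytest.approx(1.0)  # AA is the first dimer
        assert out[0, 2:].sum() == 0.0

    def test_frequencies_sum_to_one_per_k(self, rng):
        cfg = FeatureConfig(kmer_ks=(2, 3))
        seq = "".join(rng.choice(list("ACGT"), size=25))
        out = feat.f3_sequence({"x": seq}, cfg)
        assert out[0, 1:17].sum() == pytest.approx(1.0)
        assert out[0, 17:].sum() == pytest.approx(1.0)

    def test_short_sequence_zero_block(self):
        cfg = FeatureConfig(kmer_ks=(4,))
        out = feat.f3_sequence({"x": "ACG"}, cfg)
        assert out[0, 1:].sum() == 0.0


class TestF4:
    def test_rank_one_block_recovery(self):
        A_vals = np.zeros((4, 3))
        A_vals[:2, :2] = 1.0
        u, v = feat._truncated_svd_latents(A_vals, 1)
        assert np.allclose(u @ v.T, A_vals, atol=1e-9)

    def test_rank_r_pair_inner_products(self, rng):
        base = (rng.random((6, 4)) < 0.5).astype(float)
        r = np.linalg.matrix_rank(base)
        u, v = feat._truncated_svd_latents(base, int(r))
        assert np.allclose(u @ v.T, base, atol=1e-9)

    def test_bipartite_star_betweenness(self):
        # one disease connected to three circRNAs
        A = AssociationMatrix(
            ["c0", "c1", "c2"], ["d0"], np.ones((3, 1))
        )
        block = feat.f4_association(A, [(0, 0)], FeatureConfig(svd_rank=1))
        # layout: [u(1), v(1), deg_c, deg_d, bc/cc/ec circ, bc/cc/ec disease]
        bc_c, bc_d = block[0, 4], block[0, 7]
        assert bc_d > bc_c
        assert bc_c == 0.0


class TestAssemblerAndMasking:
    def test_deterministic(self, tiny_setup):
        P, DS, seqs, A, cfg = tiny_setup
        asm = PairFeatureAssembler(P, DS, seqs, cfg)
        pairs = asm.all_pairs()
        x1 = asm.feature_matrix(pairs, A)
        x2 = asm.feature_matrix(pairs, A)
        assert np.array_equal(x1, x2)

    def test_block_spans_partition_vector(self, tiny_setup):
        P, DS, seqs, A, cfg = tiny_setup
        asm = PairFeatureAssembler(P, DS, seqs, cfg)
        spans = sorted(asm.block_index.values(), key=lambda s: s.start)
        assert spans[0].start == 0
        assert spans[-1].stop == asm.n_features
        for a, b in zip(spans[:-1], spans[1:]):
            assert a.stop == b.start
        assert len(asm.feature_names()) == asm.n_features

    def test_masked_features_ignore_own_cell(self, tiny_setup):
        """Pair-view features must be identical whether the pair's own
        association bit is 0 or 1: the own cell never enters."""
        P, DS, seqs, A, cfg = tiny_setup
        asm = PairFeatureAssembler(P, DS, seqs, cfg)
        i, j = 0, 0
        assert A[i, j] == 1.0
        flipped = A.copy()
        flipped[i, j] = 0.0
        x_on = asm.feature_matrix([(i, j)], A, mask=True)
        x_off = asm.feature_matrix([(i, j)], flipped, mask=True)
        assert np.array_equal(x_on, x_off)

    def test_unmasked_features_react_only_in_assoc_blocks(self, tiny_setup):
        P, DS, seqs, A, cfg = tiny_setup
        asm = PairFeatureAssembler(P, DS, seqs, cfg)
        i, j = 0, 0
        flipped = A.copy()
        flipped[i, j] = 0.0
        x_on = asm.feature_matrix([(i, j)], A, mask=False)[0]
        x_off = asm.feature_matrix([(i, j)], flipped, mask=False)[0]
        diff = np.nonzero(x_on != x_off)[0]
        allowed = set()
        for name in ("F4_pair",):
            s = asm.block_index[name]
            allowed.update(range(s.start, s.stop))
        # degree entries of F1 and the degree-derived F2 neighbor averages
        names = asm.feature_names()
        for k, nm in enumerate(names):
            if "num.nei" in nm or nm.endswith("ave.feat1.0"):
                allowed.add(k)
        assert set(diff) <= allowed
        assert len(diff) > 0


class TestPCA:
    def test_full_variance_reconstruction_exact(self, rng):
        x = rng.normal(size=(20, 7))
        reduced, proj = pca_reduce(x, FeatureConfig(pca_variance=1.0))
        back = proj.inverse_transform(reduced)
        assert np.allclose(back, x, atol=1e-9)

    def test_explained_variance_ratios_non_increasing(self, rng):
        x = rng.normal(size=(30, 6)) * np.array([5, 4, 3, 2, 1, 0.5])
        _, proj = pca_reduce(x, FeatureConfig(pca_variance=1.0))
        evr = proj.explained_variance_ratio
        assert np.all(np.diff(evr) <= 1e-12)

    def test_rank_q_error_matches_svd_oracle(self, rng):
        x = rng.normal(size=(25, 8))
        q = 3
        reduced, proj = pca_reduce(x, FeatureConfig(pca_variance=q))
        back = proj.inverse_transform(reduced)
        # compare on the standardized scale where PCA operates
        z = (x - proj.mean) / proj.scale
        zc = z - z.mean(axis=0)
        u, s, vt = np.linalg.svd(zc, full_matrices=False)
        best = (u[:, :q] * s[:q]) @ vt[:q]
        zb = (back - proj.mean) / proj.scale - z.mean(axis=0)
        assert np.linalg.norm(zb - best) < 1e-9

    def test_projection_round_trips_through_json(self, rng):
        x = rng.normal(size=(15, 5))
        reduced, proj = pca_reduce(x, FeatureConfig(pca_variance=0.9))
        proj2 = feat.PCAProjection.from_json(proj.to_json())
        assert np.allclose(proj2.transform(x), reduced, atol=1e-12)
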