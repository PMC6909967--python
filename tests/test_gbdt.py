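import json

import numpy as np
import pytest

from circboost import gbdt
from circboost.gbdt import GBDTModel, GBDTParams

from oracles import best_split_enumerate


def _mse(y, p):
    return float(np.mean((y - p) ** 2))


class TestFit:
    def test_constant_labels_give_constant_model(self, rng):
        X = rng.normal(size=(30, 4))
        y = np.full(30, 0.7)
        m = gbdt.fit(X, y, GBDTParams(n_estimators=10, min_samples_split=2,
                                      min_samples_leaf=1, max_features=None,
                                      subsample=1.0))
        assert np.allclose(m.predict(X), 0.7)

    def test_single_stump_on_step_function(self):
        # y=(0,0,1,1) over x=(1,2,3,4): exhaustive enumeration puts the split
        # at 2.5 with leaf values -1/2 and +1/2 around F0=0.5
        X = np.array([[1.0], [2.0], [3.0], [4.0]])
        y = np.array([0.0, 0.0, 1.0, 1.0])
        params = GBDTParams(n_estimators=1, learning_rate=1.0, max_depth=1,
                            min_samples_split=2, min_samples_leaf=1,
                            max_features=None, subsample=1.0)
        m = gbdt.fit(X, y, params)
        tree = m.trees[0]
        assert tree.feature[0] == 0
        assert tree.threshold[0] == pytest.approx(2.5)
        assert sorted(tree.value[tree.feature < 0]) == pytest.approx([-0.5, 0.5])
        assert np.allclose(m.predict(X), y)

    def test_training_mse_non_increasing_without_subsampling(self, rng):
        X = rng.normal(size=(60, 5))
        y = X[:, 0] - 0.5 * X[:, 2] + rng.normal(scale=0.2, size=60)
        m = gbdt.fit(X, y, GBDTParams(n_estimators=40, subsample=1.0,
                                      max_features=None, min_samples_split=4,
                                      min_samples_leaf=2))
        mses = [_mse(y, p) for p in m.staged_predict(X)]
        assert all(b <= a + 1e-12 for a, b in zip(mses[:-1], mses[1:]))

    def test_interpolation_regime_drives_mse_below_1e3(self, rng):
        X = rng.normal(size=(50, 3))
        y = rng.normal(size=50)
        params = GBDTParams(n_estimators=200, learning_rate=0.5, subsample=1.0,
                            max_features=None, max_depth=6,
                            min_samples_split=2, min_samples_leaf=1)
        m = gbdt.fit(X, y, params)
        assert _mse(y, m.predict(X)) < 1e-3

    def test_every_split_matches_exhaustive_enumeration(self, rng):
        for trial in range(25):
            n = int(rng.integers(4, 13))
            d = int(rng.integers(1, 4))
            X = np.round(rng.normal(size=(n, d)), 2)
            y = np.round(rng.normal(size=n), 2)
            params = GBDTParams(n_estimators=1, learning_rate=1.0, max_depth=1,
                                min_samples_split=2, min_samples_leaf=1,
                                max_features=None, subsample=1.0, seed=trial)
            m = gbdt.fit(X, y, params)
            tree = m.trees[0]
            expected = best_split_enumerate(X, y - y.mean(), min_leaf=1)
            if expected is None:
                assert tree.feature[0] == -1
            else:
                assert (tree.feature[0], tree.threshold[0]) == pytest.approx(expected)

    def test_seeded_determinism_bit_exact(self, rng):
        X = rng.normal(size=(80, 6))
        y = rng.normal(size=80)
        params = GBDTParams(n_estimators=15, subsample=0.7, max_features=3, seed=42)
        m1 = gbdt.fit(X, y, params)
        m2 = gbdt.fit(X, y, params)
        assert json.dumps(m1.to_json()) == json.dumps(m2.to_json())
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_min_samples_split_above_n_gives_constant(self, rng):
        X = rng.normal(size=(10, 2))
        y = rng.normal(size=10)
        m = gbdt.fit(X, y, GBDTParams(min_samples_split=50))
        assert np.allclose(m.predict(X), y.mean())

    def test_non_finite_features_rejected(self):
        X = np.array([[1.0], [np.nan]])
        with pytest.raises(ValueError, match="non-finite"):
            gbdt.fit(X, np.array([0.0, 1.0]), GBDTParams())

    def test_agrees_with_reference_gradient_boosting(self, rng):
        from sklearn.ensemble import GradientBoostingRegressor

        X = rng.normal(size=(100, 10))
        y = X[:, 0] + 0.5 * X[:, 1] ** 2 + rng.normal(scale=0.3, size=100)
        params = GBDTParams(n_estimators=50, learning_rate=0.1, max_depth=3,
                            min_samples_split=5, min_samples_leaf=2,
                            max_features=None, subsample=1.0)
        ours = gbdt.fit(X, y, params).predict(X)
        ref = GradientBoostingRegressor(
            n_estimators=50, learning_rate=0.1, max_depth=3,
            min_samples_split=5, min_samples_leaf=2, random_state=0,
        ).fit(X, y).predict(X)
        assert _mse(ours, ref) < 1e-2


class TestPredict:
    def test_empty_tree_list_is_constant(self):
        m = GBDTModel(f0=0.3, learning_rate=0.1, n_features=2)
        assert np.allclose(m.predict(np.zeros((4, 2))), 0.3)

    def test_single_leaf_tree_shifts_by_lr_times_value(self):
        from circboost.gbdt import RegressionTree

        tree = RegressionTree(
            np.array([-1]), np.array([0.0]), np.array([-1]), np.array([-1]),
            np.array([2.0]),
        )
        m = GBDTModel(f0=1.0, learning_rate=0.1, n_features=3, trees=[tree])
        assert np.allclose(m.predict(np.zeros((5, 3))), 1.2)

    def test_json_round_trip_bit_exact(self, rng):
        X = rng.normal(size=(40, 4))
        y = rng.normal(size=40)
        m = gbdt.fit(X, y, GBDTParams(n_estimators=8, subsample=0.8,
                                      max_features=2, seed=3))
        m2 = GBDTModel.from_json(json.loads(json.dumps(m.to_json())))
        assert np.array_equal(m.predict(X), m2.predict(X))

    def test_feature_count_fingerprint_enforced(self, rng):
        X = rng.normal(size=(20, 3))
        m = gbdt.fit(X, rng.normal(size=20), GBDTParams())
        with pytest.raises(ValueError, match="mismatch"):
            m.predict(np.zeros((2, 4)))


def test_tree_structure_invariants(rng):
    X = rng.normal(size=(120, 5))
    y = rng.normal(size=120)
    params = GBDTParams(n_estimators=5, max_depth=4, min_samples_leaf=7,
                        min_samples_split=15, subsample=1.0, max_features=None)
    m = gbdt.fit(X, y, params)
    for tree in m.trees:
        # count samples reaching each leaf; every leaf >= min_samples_leaf
        counts = np.zeros(len(tree.feature), dtype=int)
        for row in X:
            node = 0
            depth = 0
            while tree.feature[node] >= 0:
                node = (
                    tree.left[node]
                    if row[tree.feature[node]] <= tree.threshold[node]
                    else tree.right[node]
                )
                depth += 1
                assert depth <= params.max_depth
            counts[node] += 1
        leaf_counts = counts[tree.feature < 0]
        assert leaf_counts.min() >= params.min_samples_leaf
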