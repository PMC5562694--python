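"""Feature ranking/selection, random forests, per-lesion scoring."""

import numpy as np
import pytest

from bladresp.models import (RFConfig, predict_scores, rank_features_by_auc,
                             score_lesion, select_features, train_random_forest)


def _two_class_data(rng, n=100, n_noise=4, effect=3.0):
    y = np.r_[np.ones(n // 2, int), np.zeros(n - n // 2, int)]
    X = rng.normal(size=(n, 2 + n_noise))
    X[:, 0] += effect * y
    X[:, 1] -= effect * y
    return X, y


class TestRanking:
    def test_perfect_feature_ranks_first(self, rng):
        X = rng.normal(size=(40, 3))
        y = np.r_[np.ones(20, int), np.zeros(20, int)]
        X[:, 2] = y * 10.0 + rng.normal(scale=0.01, size=40)
        ranked = rank_features_by_auc(X, y)
        idx, _, auc = ranked[0]
        assert idx == 2 and auc == pytest.approx(1.0)

    def test_reversed_feature_folds_to_one(self):
        y = np.r_[np.ones(10, int), np.zeros(10, int)]
        X = (1.0 - y)[:, None].astype(float)   # separates in reverse
        (_, _, auc), = rank_features_by_auc(X, y)
        assert auc == pytest.approx(1.0)

    def test_noise_feature_near_half(self, rng):
        X = rng.normal(size=(200, 1))
        y = rng.integers(0, 2, 200)
        y[:2] = [0, 1]
        (_, _, auc), = rank_features_by_auc(X, y)
        assert 0.5 <= auc <= 0.6  # folded AUC within the Mann-Whitney null band

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            rank_features_by_auc(rng.normal(size=(5, 2)), [1] * 5)


class TestSelection:
    def test_informative_features_found_across_seeds(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            y = np.r_[np.ones(60, int), np.zeros(60, int)]
            X = rng.normal(size=(120, 22))
            X[:, 3] += 1.5 * y
            X[:, 11] -= 1.5 * y
            sel = select_features(X, y, k_max=4, seed=seed,
                                  rf_config=RFConfig(6, 5, seed))
            hits += {3, 11} <= set(sel)
        assert hits >= 9

    def test_same_seed_same_subset(self, rng):
        X, y = _two_class_data(rng)
        a = select_features(X, y, k_max=3, seed=5)
        b = select_features(X, y, k_max=3, seed=5)
        assert a == b

    def test_auc_rank_method_takes_top_k(self, rng):
        X, y = _two_class_data(rng, effect=4.0)
        sel = select_features(X, y, method="auc_rank", k_max=2)
        assert set(sel) == {0, 1}

    def test_invalid_arguments(self, rng):
        X, y = _two_class_data(rng, n=20)
        with pytest.raises(ValueError):
            select_features(X, y, k_max=0)
        with pytest.raises(ValueError):
            select_features(X, y, method="bogus")


class TestRandomForest:
    def test_separable_training_auc(self, rng):
        from sklearn.metrics import roc_auc_score

        X, y = _two_class_data(rng, n=100, effect=3.0)
        model = train_random_forest(RFConfig(6, 3, seed=0), X, y)
        scores = predict_scores(model, X)
        assert np.all((scores >= 0) & (scores <= 1))
        assert roc_auc_score(y, scores) >= 0.95

    def test_configuration_honored(self, rng):
        X, y = _two_class_data(rng, n=80)
        cfg = RFConfig(n_trees=6, min_leaf=13, seed=1)
        model = train_random_forest(cfg, X, y)
        est = model.estimator
        assert len(est.estimators_) == 6
        for tree in est.estimators_:
            t = tree.tree_
            leaf_sizes = t.n_node_samples[t.children_left == -1]
            assert np.all(leaf_sizes >= 13)

    def test_row_permutation_does_not_change_predictions(self, rng):
        X, y = _two_class_data(rng, n=60)
        perm = rng.permutation(len(y))
        m1 = train_random_forest(RFConfig(6, 5, seed=3), X, y)
        m2 = train_random_forest(RFConfig(6, 5, seed=3), X[perm], y[perm])
        Xt = rng.normal(size=(10, X.shape[1]))
        np.testing.assert_allclose(predict_scores(m1, Xt), predict_scores(m2, Xt))

    def test_same_seed_identical_scores(self, rng):
        X, y = _two_class_data(rng, n=60)
        m1 = train_random_forest(RFConfig(4, 5, seed=9), X, y)
        m2 = train_random_forest(RFConfig(4, 5, seed=9), X, y)
        Xt = rng.normal(size=(15, X.shape[1]))
        np.testing.assert_array_equal(predict_scores(m1, Xt), predict_scores(m2, Xt))

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            train_random_forest(RFConfig(2, 2), rng.normal(size=(8, 2)), [1] * 8)


class TestScoreLesion:
    def test_forest_scoring_of_feature_vector(self, rng):
        from bladresp.types import FeatureVector

        X, y = _two_class_data(rng, n=60)
        model = train_random_forest(RFConfig(6, 5, seed=0), X, y)
        x = rng.normal(size=X.shape[1])
        fv = FeatureVector(tuple(f"f{i}" for i in range(len(x))), x, "SL_pct_change")
        assert score_lesion(model, fv) == pytest.approx(
            predict_scores(model, x[None, :])[0])

    def test_cnn_scoring_is_mean_of_roi_probabilities(self, rng):
        from bladresp.models.cnn import CNNConfig, train_cnn

        x = rng.normal(50, 5, (24, 32, 32))
        x[:12, :, 16:] += 25
        y = np.r_[np.ones(12, int), np.zeros(12, int)]
        model = train_cnn(CNNConfig(epochs=2, batch_size=8, seed=0), x, y)
        patches = rng.normal(50, 5, (5, 32, 32))
        expected = model.predict_proba(patches)[:, 1].mean()
        assert score_lesion(model, patches) == pytest.approx(expected)
        # permutation invariance of the per-lesion average
        perm = patches[rng.permutation(5)]
        assert score_lesion(model, perm) == pytest.approx(expected, abs=1e-6)

    def test_empty_input_rejected(self, rng):
        from bladresp.models.cnn import CNNConfig, train_cnn

        x = rng.normal(size=(8, 32, 32))
        y = np.array([0, 1] * 4)
        model = train_cnn(CNNConfig(epochs=1, batch_size=4, seed=0), x, y)
        with pytest.raises(ValueError):
            score_lesion(model, np.zeros((0, 32, 32)))
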