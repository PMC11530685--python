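"""Tests for the weighted-vote random forest."""

import numpy as np
import pandas as pd
import pytest

from sportfs.forest import (
    ForestConfig,
    TreeModel,
    WeightedRandomForestClassifier,
    build_tree,
    iterative_feature_elimination,
    noise_importance,
)

from oracle_tree import oracle_predict


class TestBuildTree:
    def test_pure_labels_yield_single_leaf(self):
        X = np.arange(8.0).reshape(-1, 1)
        tree = build_tree(X, np.zeros(8), ForestConfig(max_depth=5))
        assert tree.n_nodes == 1
        assert tree.feature[0] == -1

    def test_separable_single_feature_is_a_stump(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        tree = build_tree(X, y, ForestConfig(max_depth=10, features_per_split="all"))
        assert tree.n_nodes == 3
        assert tree.threshold[0] == pytest.approx(1.5)
        assert np.array_equal(tree.predict_codes(X), y)

    def test_matches_exhaustive_oracle_on_random_binary_data(self, rng):
        for _ in range(60):
            n = int(rng.integers(2, 9))
            X = rng.integers(0, 2, (n, 4)).astype(float)
            y = rng.integers(0, 2, n)
            tree = build_tree(
                X, y, ForestConfig(max_depth=64, features_per_split="all")
            )
            classes = np.unique(y)
            got = classes[tree.predict_codes(X)]
            want = oracle_predict(X.astype(int).tolist(), y.tolist())
            assert list(got) == want

    def test_scale_free_importance_under_sample_duplication(self, small_cohort):
        X = small_cohort.features.to_numpy()
        y = small_cohort.labels.to_numpy()
        cfg = ForestConfig(max_depth=30, features_per_split="all", seed=4)
        t1 = build_tree(X, y, cfg)
        t2 = build_tree(np.vstack([X, X]), np.concatenate([y, y]), cfg)
        n1 = t1.vim_mdi / t1.vim_mdi.sum()
        n2 = t2.vim_mdi / t2.vim_mdi.sum()
        assert np.allclose(n1, n2, atol=1e-9)


class TestForestFit:
    def test_single_tree_forest_equals_its_tree(self, small_cohort):
        est = WeightedRandomForestClassifier(n_trees=1, random_state=0).fit(
            small_cohort.features, small_cohort.labels.to_numpy()
        )
        X = small_cohort.features.to_numpy()
        tree_pred = est.classes_[est.trees_[0].predict_codes(X)]
        assert np.array_equal(est.predict(small_cohort.features), tree_pred)
        assert est.tree_weights_ == pytest.approx([1.0])

    def test_oob_error_matches_direct_recount(self, small_cohort, small_forest):
        X = small_cohort.features.to_numpy()
        y = small_cohort.labels.to_numpy()
        _, y_codes = np.unique(y, return_inverse=True)
        for tree in small_forest.trees_:
            oob = tree.oob_idx
            assert set(oob) == set(range(len(y))) - set(tree.in_bag_idx)
            recount = float(np.mean(tree.predict_codes(X[oob]) != y_codes[oob]))
            assert tree.oob_error == pytest.approx(recount)

    def test_weights_are_normalized_and_track_oob_accuracy(self, small_forest):
        w = small_forest.tree_weights_
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0)
        acc = 1.0 - small_forest.oob_errors_
        assert np.allclose(w, acc / acc.sum())

    def test_unlimited_depth_trees_fit_their_in_bag_samples_perfectly(self, rng):
        X = rng.normal(size=(120, 3))
        y = (X[:, 0] > 0).astype(int)  # noise-free separable
        est = WeightedRandomForestClassifier(
            n_trees=10, max_depth=50, random_state=1
        ).fit(X, y)
        for tree in est.trees_:
            in_bag = tree.in_bag_idx
            assert np.array_equal(tree.predict_codes(X[in_bag]), y[in_bag])

    def test_determinism_under_fixed_seed(self, small_cohort):
        def fit():
            return WeightedRandomForestClassifier(
                n_trees=8, random_state=123
            ).fit(small_cohort.features, small_cohort.labels.to_numpy())

        a, b = fit(), fit()
        assert np.array_equal(a.predict(small_cohort.features),
                              b.predict(small_cohort.features))
        assert np.allclose(a.feature_importances_, b.feature_importances_)
        assert np.allclose(a.tree_weights_, b.tree_weights_)

    def test_validation_errors(self, small_cohort):
        est = WeightedRandomForestClassifier(n_trees=0)
        with pytest.raises(ValueError):
            est.fit(small_cohort.features, small_cohort.labels)
        X = small_cohort.features.copy()
        X.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="NaN"):
            WeightedRandomForestClassifier().fit(X, small_cohort.labels)


class TestWeightedVoting:
    @staticmethod
    def _leaf_tree(class_counts):
        return TreeModel(
            feature=np.array([-1]), threshold=np.zeros(1),
            left=np.array([-1]), right=np.array([-1]),
            value=np.array([class_counts], dtype=float),
            node_gini=np.zeros(1), in_bag_idx=np.arange(4),
            oob_idx=np.empty(0, np.int64), oob_error=0.0,
            vim_printed=np.zeros(2), vim_mdi=np.zeros(2),
        )

    def _manual_forest(self, weights, trees):
        est = WeightedRandomForestClassifier(n_trees=len(trees))
        est.classes_ = np.array(["neg", "pos"])
        est.feature_names_in_ = np.array(["a", "b"], dtype=object)
        est.n_features_in_ = 2
        est.trees_ = trees
        est.tree_weights_ = np.asarray(weights, dtype=float)
        est.oob_errors_ = np.zeros(len(trees))
        est.feature_importances_ = np.array([0.5, 0.5])
        est._X_shape = (4, 2)
        return est

    def test_unanimous_trees_give_full_share(self):
        est = self._manual_forest(
            [0.5, 0.5], [self._leaf_tree([0, 4]), self._leaf_tree([1, 5])]
        )
        X = np.zeros((3, 2))
        shares = est.vote_shares(X)
        assert np.allclose(shares[:, 1], 1.0)
        assert list(est.predict(X)) == ["pos"] * 3

    def test_disagreeing_trees_follow_the_heavier_weight(self):
        est = self._manual_forest(
            [0.9, 0.1], [self._leaf_tree([4, 0]), self._leaf_tree([0, 4])]
        )
        X = np.zeros((1, 2))
        assert est.predict(X)[0] == "neg"
        assert est.vote_shares(X)[0] == pytest.approx([0.9, 0.1])

    def test_five_tree_tally_matches_hand_computation(self):
        weights = [0.3, 0.25, 0.2, 0.15, 0.1]
        votes = [1, 0, 1, 0, 0]  # class index each tree returns
        trees = [self._leaf_tree([1, 0] if v == 0 else [0, 1]) for v in votes]
        est = self._manual_forest(weights, trees)
        share_pos = sum(w for w, v in zip(weights, votes) if v == 1)
        got = est.vote_shares(np.zeros((1, 2)))[0]
        assert got[1] == pytest.approx(share_pos)
        assert est.predict(np.zeros((1, 2)))[0] == "neg"

    def test_uniform_weights_reduce_to_majority_vote(self, small_cohort):
        est = WeightedRandomForestClassifier(
            n_trees=9, tree_weighting="uniform", random_state=2
        ).fit(small_cohort.features, small_cohort.labels.to_numpy())
        X = small_cohort.features.to_numpy()[:50]
        votes = np.stack([t.predict_codes(X) for t in est.trees_])
        majority = np.array([np.bincount(v, minlength=2).argmax()
                             for v in votes.T])
        assert np.array_equal(est.predict(X), est.classes_[majority])

    def test_missing_feature_column_rejected(self, small_forest, small_cohort):
        X = small_cohort.features.drop(columns=[small_cohort.features.columns[0]])
        with pytest.raises(ValueError, match="missing feature columns"):
            small_forest.predict(X)


class TestNoiseImportance:
    def test_unused_feature_scores_near_zero_and_sole_predictor_positive(self, rng):
        n = 400
        X = pd.DataFrame({
            "signal": rng.normal(size=n),
            "idle": rng.normal(size=n),
        })
        y = (X["signal"] > 0).astype(int).to_numpy()
        est = WeightedRandomForestClassifier(
            n_trees=30, max_depth=1, features_per_split="all", random_state=3
        ).fit(X, y)
        idle = noise_importance(est, X, y, "idle", rng=0)
        sig = noise_importance(est, X, y, "signal", rng=0)
        assert abs(idle) < 2 / np.sqrt(n)
        assert sig > 0.2

    def test_matches_independent_recount_with_shared_permutations(
        self, small_cohort, small_forest
    ):
        X = small_forest._check_X(small_cohort.features)
        y = small_cohort.labels.to_numpy()
        _, y_codes = np.unique(y, return_inverse=True)
        feature = list(small_forest.feature_names_in_).index(
            sorted(small_cohort.truth)[0]
        )
        got = noise_importance(small_forest, small_cohort.features,
                               y, feature, rng=77)
        rng = np.random.default_rng(77)  # replay the same permutation stream
        deltas = []
        for tree in small_forest.trees_:
            oob = tree.oob_idx
            Xo = X[oob]
            base = np.mean(tree.predict_codes(Xo) != y_codes[oob])
            Xp = Xo.copy()
            Xp[:, feature] = Xp[rng.permutation(oob.size), feature]
            pert = np.mean(tree.predict_codes(Xp) != y_codes[oob])
            deltas.append(pert - base)
        assert got == pytest.approx(float(np.mean(deltas)))

    def test_unknown_feature_rejected(self, small_forest, small_cohort):
        with pytest.raises(ValueError, match="unknown feature"):
            noise_importance(small_forest, small_cohort.features,
                             small_cohort.labels.to_numpy(), "nope")


class TestIterativeElimination:
    def test_round_sizes_count_down_by_one_for_small_fractions(self, small_cohort):
        traj = iterative_feature_elimination(
            small_cohort.features.iloc[:, :10], small_cohort.labels.to_numpy(),
            ForestConfig(n_trees=5, max_depth=6, seed=0),
            removal_fraction=0.05, rounds=4, cv=2,
        )
        assert [len(r.features) for r in traj] == [10, 9, 8, 7]

    def test_removal_matches_the_importance_ranking_of_the_same_round(
        self, small_cohort
    ):
        traj = iterative_feature_elimination(
            small_cohort.features, small_cohort.labels.to_numpy(),
            ForestConfig(n_trees=10, max_depth=8, seed=1),
            removal_fraction=0.25, rounds=3, cv=2,
        )
        for this_round, next_round in zip(traj, traj[1:]):
            k = len(this_round.removed)
            bottom = sorted(this_round.importances,
                            key=this_round.importances.get)[:k]
            assert sorted(this_round.removed) == sorted(bottom)
            assert set(next_round.features) == (
                set(this_round.features) - set(this_round.removed)
            )

    def test_planted_features_survive_early_rounds(self, small_cohort):
        traj = iterative_feature_elimination(
            small_cohort.features, small_cohort.labels.to_numpy(),
            ForestConfig(n_trees=30, max_depth=12, seed=2),
            removal_fraction=0.2, rounds=3, cv=2,
        )
        assert small_cohort.truth <= set(traj[-1].features)


class TestSerialization:
    def test_json_round_trip_preserves_predictions(self, small_cohort, small_forest):
        text = small_forest.to_json()
        restored = WeightedRandomForestClassifier.from_json(text)
        X = small_cohort.features
        assert np.array_equal(small_forest.predict(X), restored.predict(X))
        assert np.allclose(small_forest.tree_weights_, restored.tree_weights_)
        assert np.allclose(small_forest.feature_importances_,
                           restored.feature_importances_)
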