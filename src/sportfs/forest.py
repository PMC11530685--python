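"""Weighted-vote random forest with Gini importance and feature elimination.

The classifier grows information-gain trees on bootstrap resamples with a
random feature subset at every node.  Each tree then receives a scalar
voting weight proportional to its out-of-bag (OOB) accuracy, normalized to
sum to one; forest predictions are the argmax of the weight-summed one-hot
tree votes, so a 1 x n_trees weight row is effectively convolved with the
n_trees x K vote matrix.  With uniform weights this reduces to the ordinary
majority vote.

Feature relevance comes out of the forest along two routes: impurity-based
importance accumulated while growing (see :mod:`sportfs._tree` for the two
accumulators), and noise-perturbation importance, where a feature's OOB
column is permuted and the growth in OOB error is averaged over trees.
Iterative elimination repeatedly drops the lowest-importance fraction of
features and records the cross-validated accuracy trajectory.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from . import _tree
from .impurity import aggregate_and_normalize_importance

__all__ = [
    "TreeModel",
    "ForestConfig",
    "WeightedRandomForestClassifier",
    "build_tree",
    "fit_forest",
    "predict",
    "noise_importance",
    "iterative_feature_elimination",
    "EliminationRound",
]


@dataclass
class TreeModel:
    """One grown tree: flat node arrays plus bootstrap bookkeeping."""

    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray  # per-node class counts (in-bag)
    node_gini: np.ndarray
    in_bag_idx: np.ndarray
    oob_idx: np.ndarray
    oob_error: float
    vim_printed: np.ndarray
    vim_mdi: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.feature.shape[0]

    def apply(self, X: np.ndarray) -> np.ndarray:
        return _tree.apply_tree(self.feature, self.threshold, self.left, self.right,
                                np.ascontiguousarray(X, dtype=np.float64))

    def predict_codes(self, X: np.ndarray) -> np.ndarray:
        """Majority class index at the reached leaf (ties -> lowest index)."""
        return np.argmax(self.value[self.apply(X)], axis=1)

    def to_dict(self) -> dict:
        return {
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "value": self.value.tolist(),
            "node_gini": self.node_gini.tolist(),
            "in_bag_idx": self.in_bag_idx.tolist(),
            "oob_error": self.oob_error,
            "vim_printed": self.vim_printed.tolist(),
            "vim_mdi": self.vim_mdi.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict, n_samples: int) -> "TreeModel":
        in_bag = np.asarray(d["in_bag_idx"], dtype=np.int64)
        oob = np.setdiff1d(np.arange(n_samples), in_bag)
        return cls(
            feature=np.asarray(d["feature"], dtype=np.int64),
            threshold=np.asarray(d["threshold"], dtype=float),
            left=np.asarray(d["left"], dtype=np.int64),
            right=np.asarray(d["right"], dtype=np.int64),
            value=np.asarray(d["value"], dtype=float),
            node_gini=np.asarray(d["node_gini"], dtype=float),
            in_bag_idx=in_bag,
            oob_idx=oob,
            oob_error=float(d["oob_error"]),
            vim_printed=np.asarray(d["vim_printed"], dtype=float),
            vim_mdi=np.asarray(d["vim_mdi"], dtype=float),
        )


@dataclass(frozen=True)
class ForestConfig:
    """Forest hyperparameters (the grid-search axes plus growth controls)."""

    n_trees: int = 100
    max_depth: int = 20
    features_per_split: int | str | None = "sqrt"
    min_samples_leaf: int = 1
    removal_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if isinstance(self.features_per_split, int) and self.features_per_split < 1:
            raise ValueError("features_per_split must be >= 1")
        if self.min_samples_leaf < 1:
            raise ValueError("min_samples_leaf must be >= 1")
        if not 0.0 < self.removal_fraction < 1.0:
            raise ValueError("removal_fraction must lie strictly in (0, 1)")

    def estimator(self) -> "WeightedRandomForestClassifier":
        return WeightedRandomForestClassifier(
            n_trees=self.n_trees,
            max_depth=self.max_depth,
            features_per_split=self.features_per_split,
            min_samples_leaf=self.min_samples_leaf,
            random_state=self.seed,
        )


def _resolve_mtry(features_per_split, d: int) -> int:
    if features_per_split in (None, "all"):
        return d
    if features_per_split == "sqrt":
        return int(math.ceil(math.sqrt(d)))
    m = int(features_per_split)
    if m < 1:
        raise ValueError("features_per_split must be >= 1")
    return min(m, d)


class WeightedRandomForestClassifier(BaseEstimator, ClassifierMixin):
    """Random forest with OOB-accuracy-weighted tree voting.

    Parameters
    ----------
    n_trees : int
        Number of bootstrap trees.
    max_depth : int
        Maximum tree depth (root = depth 0).
    features_per_split : int, "sqrt", "all" or None
        Features sampled without replacement at each node; ``"sqrt"``
        (default) uses ``ceil(sqrt(d))``, ``"all"``/None disables subsetting.
    min_samples_leaf : int
        Minimum samples in each child of a split.
    tree_weighting : {"oob", "uniform"}
        "oob" weights trees by OOB accuracy (normalized to sum 1);
        "uniform" gives every tree weight 1/n_trees.
    importance : {"mdi", "as_printed"}
        Which per-node Gini accumulation feeds ``feature_importances_``:
        the standard node-fraction-weighted mean decrease in impurity, or the
        raw unweighted delta ``Gini_m - Gini_l - Gini_r`` summed as-is.
    random_state : int or None
        Seed for bootstraps and per-node feature subsets.

    Attributes
    ----------
    classes_ : ndarray of class labels.
    trees_ : list of :class:`TreeModel`.
    tree_weights_ : ndarray, nonnegative, summing to 1.
    oob_errors_ : per-tree OOB misclassification rate.
    feature_importances_ : normalized per-feature scores summing to 1.
    """

    def __init__(
        self,
        n_trees: int = 100,
        max_depth: int = 20,
        features_per_split="sqrt",
        min_samples_leaf: int = 1,
        tree_weighting: str = "oob",
        importance: str = "mdi",
        random_state=None,
    ):
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.features_per_split = features_per_split
        self.min_samples_leaf = min_samples_leaf
        self.tree_weighting = tree_weighting
        self.importance = importance
        self.random_state = random_state

    # -- fitting -----------------------------------------------------------

    def _validate_Xy(self, X, y):
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            X = X.to_numpy(dtype=np.float64)
        else:
            X = np.asarray(X, dtype=np.float64)
            if X.ndim != 2:
                raise ValueError("X must be 2-dimensional")
            self.feature_names_in_ = np.asarray(
                [f"x{j}" for j in range(X.shape[1])], dtype=object
            )
        if np.isnan(X).any():
            raise ValueError("X contains NaN; run preprocessing first")
        y = np.asarray(y).ravel()
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y have different numbers of samples")
        if X.shape[0] < 1 or X.shape[1] < 1:
            raise ValueError("need at least one sample and one feature")
        return X, y

    def fit(self, X, y):
        if self.n_trees < 1 or self.max_depth < 1 or self.min_samples_leaf < 1:
            raise ValueError("n_trees, max_depth and min_samples_leaf must be >= 1")
        if self.tree_weighting not in ("oob", "uniform"):
            raise ValueError("tree_weighting must be 'oob' or 'uniform'")
        if self.importance not in ("mdi", "as_printed"):
            raise ValueError("importance must be 'mdi' or 'as_printed'")
        X, y = self._validate_Xy(X, y)
        n, d = X.shape
        self.n_features_in_ = d
        self.classes_, y_codes = np.unique(y, return_inverse=True)
        y_codes = y_codes.astype(np.int64)
        n_classes = self.classes_.size
        mtry = _resolve_mtry(self.features_per_split, d)
        if n < 2 * self.min_samples_leaf:
            raise ValueError(
                f"dataset of {n} samples is smaller than 2*min_samples_leaf"
            )

        XT = np.ascontiguousarray(X.T)
        rng = np.random.default_rng(self.random_state)
        trees: list[TreeModel] = []
        accuracies = np.empty(self.n_trees)
        all_idx = np.arange(n)
        for _ in range(self.n_trees):
            in_bag = rng.integers(0, n, n).astype(np.int64)
            tree_seed = int(rng.integers(0, 2**31 - 1))
            (feat, thr, left, right, value, node_gini, n_nodes,
             vim_printed, vim_mdi) = _tree.grow_tree(
                XT, y_codes, n_classes, self.max_depth, mtry,
                self.min_samples_leaf, tree_seed, in_bag,
            )
            oob = np.setdiff1d(all_idx, in_bag, assume_unique=False)
            tree = TreeModel(
                feature=feat, threshold=thr, left=left, right=right,
                value=value, node_gini=node_gini,
                in_bag_idx=in_bag, oob_idx=oob, oob_error=np.nan,
                vim_printed=vim_printed, vim_mdi=vim_mdi,
            )
            if oob.size > 0:
                pred = tree.predict_codes(X[oob])
                err = float(np.mean(pred != y_codes[oob]))
            else:
                warnings.warn(
                    "tree has no OOB samples; weighting it by in-bag accuracy",
                    RuntimeWarning,
                    stacklevel=2,
                )
                pred = tree.predict_codes(X[in_bag])
                err = float(np.mean(pred != y_codes[in_bag]))
            tree.oob_error = err
            accuracies[len(trees)] = 1.0 - err
            trees.append(tree)

        self.trees_ = trees
        self.oob_errors_ = np.array([t.oob_error for t in trees])
        if self.tree_weighting == "uniform" or accuracies.sum() <= 0.0:
            self.tree_weights_ = np.full(self.n_trees, 1.0 / self.n_trees)
        else:
            self.tree_weights_ = accuracies / accuracies.sum()
        key = "vim_mdi" if self.importance == "mdi" else "vim_printed"
        self.feature_importances_ = aggregate_and_normalize_importance(
            [getattr(t, key) for t in trees], n_features=d
        )
        self._y_codes = y_codes
        self._X_shape = (n, d)
        return self

    # -- prediction --------------------------------------------------------

    def _check_X(self, X):
        check_is_fitted(self, "trees_")
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names_in_ if c not in X.columns]
            if missing:
                raise ValueError(f"missing feature columns: {missing}")
            X = X.loc[:, list(self.feature_names_in_)].to_numpy(dtype=np.float64)
        else:
            X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X must have {self.n_features_in_} feature columns"
            )
        return X

    def vote_shares(self, X) -> np.ndarray:
        """Per-class weighted vote shares (rows sum to 1)."""
        X = self._check_X(X)
        shares = np.zeros((X.shape[0], self.classes_.size))
        for w, tree in zip(self.tree_weights_, self.trees_):
            votes = tree.predict_codes(X)
            shares[np.arange(X.shape[0]), votes] += w
        total = shares.sum(axis=1, keepdims=True)
        return shares / total

    predict_proba = vote_shares

    def predict(self, X):
        shares = self.vote_shares(X)
        return self.classes_[np.argmax(shares, axis=1)]

    # -- serialization -----------------------------------------------------

    def to_json(self, path=None) -> str:
        """Serialize the fitted forest to a documented JSON schema.

        Top-level keys: ``params`` (constructor arguments), ``classes``,
        ``feature_names``, ``n_samples``, ``tree_weights`` and ``trees``
        (flat node arrays per tree; ``feature == -1`` marks leaves).
        """
        check_is_fitted(self, "trees_")
        payload = {
            "schema": "sportfs-forest-v1",
            "params": self.get_params(),
            "classes": [str(c) for c in self.classes_],
            "feature_names": [str(c) for c in self.feature_names_in_],
            "n_samples": self._X_shape[0],
            "tree_weights": self.tree_weights_.tolist(),
            "trees": [t.to_dict() for t in self.trees_],
        }
        text = json.dumps(payload)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source) -> "WeightedRandomForestClassifier":
        text = Path(source).read_text() if isinstance(source, (str, Path)) and str(
            source
        ).endswith(".json") else source
        payload = json.loads(text)
        if payload.get("schema") != "sportfs-forest-v1":
            raise ValueError("unrecognized forest serialization schema")
        est = cls(**payload["params"])
        est.classes_ = np.asarray(payload["classes"], dtype=object)
        est.feature_names_in_ = np.asarray(payload["feature_names"], dtype=object)
        n = int(payload["n_samples"])
        est.trees_ = [TreeModel.from_dict(t, n) for t in payload["trees"]]
        est.tree_weights_ = np.asarray(payload["tree_weights"], dtype=float)
        est.oob_errors_ = np.array([t.oob_error for t in est.trees_])
        est.n_features_in_ = est.feature_names_in_.size
        est._X_shape = (n, est.n_features_in_)
        key = "vim_mdi" if est.importance == "mdi" else "vim_printed"
        est.feature_importances_ = aggregate_and_normalize_importance(
            [getattr(t, key) for t in est.trees_], n_features=est.n_features_in_
        )
        return est

    def importance_frame(self) -> pd.DataFrame:
        """Per-feature raw and normalized importance, ranked (rank 1 = top)."""
        check_is_fitted(self, "trees_")
        key = "vim_mdi" if self.importance == "mdi" else "vim_printed"
        raw = np.sum([getattr(t, key) for t in self.trees_], axis=0)
        frame = pd.DataFrame(
            {
                "feature": self.feature_names_in_,
                "raw_score": raw,
                "normalized_score": self.feature_importances_,
            }
        )
        frame = frame.sort_values(
            ["normalized_score", "feature"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)
        frame["rank"] = np.arange(1, len(frame) + 1)
        return frame


# -- functional wrappers ---------------------------------------------------


def build_tree(X, y, config: ForestConfig, rng=None) -> TreeModel:
    """Grow a single tree on the full sample (no bootstrap)."""
    config.validate()
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y).ravel()
    if X.size == 0 or y.size == 0:
        raise ValueError("X and y must be non-empty")
    classes, y_codes = np.unique(y, return_inverse=True)
    rng = np.random.default_rng(config.seed if rng is None else rng)
    mtry = _resolve_mtry(config.features_per_split, X.shape[1])
    idx = np.arange(X.shape[0], dtype=np.int64)
    (feat, thr, left, right, value, node_gini, n_nodes,
     vim_printed, vim_mdi) = _tree.grow_tree(
        np.ascontiguousarray(X.T), y_codes.astype(np.int64), classes.size,
        config.max_depth, mtry, config.min_samples_leaf,
        int(rng.integers(0, 2**31 - 1)), idx,
    )
    return TreeModel(
        feature=feat, threshold=thr, left=left, right=right, value=value,
        node_gini=node_gini, in_bag_idx=idx, oob_idx=np.empty(0, np.int64),
        oob_error=np.nan, vim_printed=vim_printed, vim_mdi=vim_mdi,
    )


def fit_forest(X, y, config: ForestConfig) -> WeightedRandomForestClassifier:
    config.validate()
    return config.estimator().fit(X, y)


def predict(forest: WeightedRandomForestClassifier, X):
    """Class labels and per-class weighted vote shares."""
    return forest.predict(X), forest.vote_shares(X)


def noise_importance(
    forest: WeightedRandomForestClassifier,
    X,
    y,
    feature,
    rng=None,
    mode: str = "permute",
    noise_scale: float = 1.0,
) -> float:
    """Noise-perturbation importance of one feature.

    Mean over trees of (OOB error with the feature column perturbed on the
    tree's OOB samples) minus (the tree's baseline OOB error on the same
    samples).  ``mode="permute"`` shuffles the column within the OOB set,
    which destroys the feature-label association while keeping the marginal
    distribution; ``mode="gaussian"`` instead adds N(0, (noise_scale*SD)^2).
    """
    check_is_fitted(forest, "trees_")
    if mode not in ("permute", "gaussian"):
        raise ValueError("mode must be 'permute' or 'gaussian'")
    names = list(forest.feature_names_in_)
    if isinstance(feature, str):
        if feature not in names:
            raise ValueError(f"unknown feature {feature!r}")
        j = names.index(feature)
    else:
        j = int(feature)
        if not 0 <= j < forest.n_features_in_:
            raise ValueError(f"feature index {j} out of range")
    X = forest._check_X(X)
    y = np.asarray(y).ravel()
    y_codes = np.searchsorted(forest.classes_, y)
    rng = np.random.default_rng(rng)
    col_sd = float(X[:, j].std())
    deltas = []
    for tree in forest.trees_:
        oob = tree.oob_idx
        if oob.size == 0:
            continue
        Xo = X[oob]
        base_err = float(np.mean(tree.predict_codes(Xo) != y_codes[oob]))
        Xp = Xo.copy()
        if mode == "permute":
            Xp[:, j] = Xp[rng.permutation(oob.size), j]
        else:
            Xp[:, j] = Xp[:, j] + rng.normal(0.0, noise_scale * col_sd, oob.size)
        pert_err = float(np.mean(tree.predict_codes(Xp) != y_codes[oob]))
        deltas.append(pert_err - base_err)
    if not deltas:
        raise ValueError("no tree has OOB samples; cannot score noise importance")
    return float(np.mean(deltas))


@dataclass(frozen=True)
class EliminationRound:
    """State of one elimination round (before removal happened)."""

    features: tuple[str, ...]
    cv_accuracy: float
    importances: dict[str, float] = field(repr=False)
    removed: tuple[str, ...] = ()


def iterative_feature_elimination(
    X,
    y,
    config: ForestConfig,
    removal_fraction: float | None = None,
    rounds: int | None = None,
    cv: int = 5,
) -> list[EliminationRound]:
    """Repeatedly drop the lowest-importance fraction of features.

    Each round fits a forest on the surviving features, records the
    stratified ``cv``-fold accuracy and normalized importance ranking, then
    removes the bottom ``ceil(fraction * n_current)`` features.  Stops after
    ``rounds`` rounds (None = until one feature is left).
    """
    config.validate()
    fraction = config.removal_fraction if removal_fraction is None else removal_fraction
    if not 0.0 < fraction < 1.0:
        raise ValueError("removal_fraction must lie strictly in (0, 1)")
    if isinstance(X, pd.DataFrame):
        frame = X.copy()
    else:
        X = np.asarray(X, dtype=float)
        frame = pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])
    y = np.asarray(y).ravel()
    trajectory: list[EliminationRound] = []
    current = list(frame.columns)
    round_no = 0
    while len(current) >= 1:
        est = ForestConfig(
            n_trees=config.n_trees, max_depth=config.max_depth,
            features_per_split=config.features_per_split,
            min_samples_leaf=config.min_samples_leaf,
            seed=config.seed + round_no,
        ).estimator()
        sub = frame.loc[:, current]
        skf = StratifiedKFold(n_splits=cv, shuffle=True,
                              random_state=config.seed + round_no)
        accs = []
        for train_idx, test_idx in skf.split(sub, y):
            est.fit(sub.iloc[train_idx], y[train_idx])
            accs.append(
                float(np.mean(est.predict(sub.iloc[test_idx]) == y[test_idx]))
            )
        est.fit(sub, y)
        imps = dict(zip(current, est.feature_importances_))
        n_remove = int(math.ceil(fraction * len(current)))
        # ascending importance, ties by column order (stable sort)
        order = sorted(range(len(current)), key=lambda i: imps[current[i]])
        removed = tuple(current[i] for i in order[:n_remove]) if len(current) > 1 else ()
        trajectory.append(
            EliminationRound(
                features=tuple(current),
                cv_accuracy=float(np.mean(accs)),
                importances=imps,
                removed=removed,
            )
        )
        round_no += 1
        if len(current) == 1 or (rounds is not None and round_no >= rounds):
            break
        current = [c for c in current if c not in removed]
    return trajectory
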