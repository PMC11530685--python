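"""End-to-end evaluation protocol: preprocess, split, tune, score, report.

The pipeline mirrors a standard cohort-study protocol for tabular fitness
data: mean-impute missing cells, drop rows containing any cell beyond three
standard deviations, split 70/30 stratified by class, select forest
hyperparameters by grid search with stratified 5-fold cross-validation (or
by the raindrop optimizer), and report accuracy / precision / recall / F1
on the held-out split together with the feature-importance ranking and its
top@k precision against the planted ground truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, train_test_split

from .datagen import LabeledDataset
from .forest import ForestConfig, WeightedRandomForestClassifier
from .impurity import pearson
from .optim import OptimizerConfig, SearchSpace, optimize

__all__ = [
    "PreprocessReport",
    "GridSearchResult",
    "MetricsReport",
    "EvaluationReport",
    "preprocess",
    "split",
    "grid_search",
    "tune_with_ara",
    "compute_metrics",
    "topk_precision",
    "effect_report",
    "DEFAULT_TREE_GRID",
    "DEFAULT_DEPTH_GRID",
]

DEFAULT_TREE_GRID = (50, 100, 150, 200)
DEFAULT_DEPTH_GRID = (10, 20, 30, 40)


# -- preprocessing ---------------------------------------------------------


@dataclass
class PreprocessReport:
    """What imputation and the 3-sigma screen did to the table."""

    imputed_cells: dict[str, int]
    removed_rows: list[int]
    column_means: dict[str, float]
    column_sds: dict[str, float]

    @property
    def n_imputed(self) -> int:
        return int(sum(self.imputed_cells.values()))

    @property
    def n_removed(self) -> int:
        return len(self.removed_rows)


def preprocess(dataset: LabeledDataset) -> tuple[LabeledDataset, PreprocessReport]:
    """Mean-impute missing cells, then drop rows with any |z| > 3 cell.

    Imputation runs first; the z-screen uses the post-imputation column
    means and SDs, computed once (no iterative re-screening).  The label
    column takes no part in either step.
    """
    frame = dataset.features.copy()
    imputed = {}
    for col in frame.columns:
        series = frame[col]
        n_missing = int(series.isna().sum())
        if n_missing == len(series):
            raise ValueError(f"column {col!r} is entirely missing; cannot impute")
        if n_missing:
            frame[col] = series.fillna(series.mean())
        imputed[col] = n_missing
    means = frame.mean()
    sds = frame.std(ddof=0).replace(0.0, np.nan)
    z = (frame - means) / sds
    outlier_row = z.abs().gt(3.0).any(axis=1)
    removed = list(frame.index[outlier_row])
    clean = LabeledDataset(
        frame.loc[~outlier_row].reset_index(drop=True),
        dataset.labels.loc[~outlier_row].reset_index(drop=True),
        dataset.truth,
    )
    report = PreprocessReport(
        imputed_cells=imputed,
        removed_rows=removed,
        column_means={c: float(means[c]) for c in frame.columns},
        column_sds={c: float(sds[c]) if np.isfinite(sds[c]) else 0.0
                    for c in frame.columns},
    )
    return clean, report


def split(dataset: LabeledDataset, ratio: float = 0.7, seed: int = 0):
    """Stratified train/test split; ``ratio`` is the training fraction."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie strictly in (0, 1)")
    idx = np.arange(dataset.n_samples)
    y = dataset.labels.to_numpy()
    train_idx, test_idx = train_test_split(
        idx, train_size=ratio, stratify=y, random_state=seed
    )
    train_idx.sort()
    test_idx.sort()
    def take(ix):
        return LabeledDataset(
            dataset.features.iloc[ix].reset_index(drop=True),
            dataset.labels.iloc[ix].reset_index(drop=True),
            dataset.truth,
        )
    train, test = take(train_idx), take(test_idx)
    for side, name in ((train, "train"), (test, "test")):
        if len(np.unique(side.labels)) < len(np.unique(y)):
            warnings.warn(f"a class is absent from the {name} split",
                          RuntimeWarning, stacklevel=2)
    return train, test


# -- model selection -------------------------------------------------------


@dataclass
class GridSearchResult:
    """Per-cell mean CV accuracy over a (n_trees, max_depth) grid."""

    cells: list[dict]
    best_n_trees: int
    best_max_depth: int
    best_accuracy: float

    def accuracy(self, n_trees: int, max_depth: int) -> float:
        for cell in self.cells:
            if cell["n_trees"] == n_trees and cell["max_depth"] == max_depth:
                return cell["mean_accuracy"]
        raise KeyError((n_trees, max_depth))

    def best_config(self, seed: int = 0, **kwargs) -> ForestConfig:
        return ForestConfig(n_trees=self.best_n_trees,
                            max_depth=self.best_max_depth, seed=seed, **kwargs)


def _cv_accuracy(features: pd.DataFrame, y: np.ndarray, config: ForestConfig,
                 folds) -> tuple[float, list[float]]:
    accs = []
    for k, (tr, te) in enumerate(folds):
        est = ForestConfig(
            n_trees=config.n_trees, max_depth=config.max_depth,
            features_per_split=config.features_per_split,
            min_samples_leaf=config.min_samples_leaf,
            seed=config.seed + 1000 * k,
        ).estimator()
        est.fit(features.iloc[tr], y[tr])
        accs.append(float(np.mean(est.predict(features.iloc[te]) == y[te])))
    return float(np.mean(accs)), accs


def grid_search(
    train: LabeledDataset,
    tree_grid=DEFAULT_TREE_GRID,
    depth_grid=DEFAULT_DEPTH_GRID,
    k_folds: int = 5,
    seed: int = 0,
    features_per_split="sqrt",
) -> GridSearchResult:
    """Mean stratified k-fold CV accuracy for every (n_trees, max_depth) cell.

    The folds are drawn once and shared by all cells, so cell comparisons
    are paired.  Ties prefer the smaller model: fewer trees, then shallower.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    y = train.labels.to_numpy()
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(train.features, y))
    for _, te in folds:
        if len(np.unique(y[te])) < 2:
            warnings.warn("a CV fold contains a single class", RuntimeWarning,
                          stacklevel=2)
    cells = []
    for n_trees in tree_grid:
        for depth in depth_grid:
            cfg = ForestConfig(n_trees=n_trees, max_depth=depth,
                               features_per_split=features_per_split, seed=seed)
            mean_acc, accs = _cv_accuracy(train.features, y, cfg, folds)
            cells.append({
                "n_trees": int(n_trees),
                "max_depth": int(depth),
                "mean_accuracy": mean_acc,
                "fold_accuracies": accs,
            })
    best = max(
        cells,
        key=lambda c: (c["mean_accuracy"], -c["n_trees"], -c["max_depth"]),
    )
    return GridSearchResult(
        cells=cells,
        best_n_trees=best["n_trees"],
        best_max_depth=best["max_depth"],
        best_accuracy=best["mean_accuracy"],
    )


def tune_with_ara(
    train: LabeledDataset,
    bounds: dict[str, tuple[float, float]] | None = None,
    budget: int = 20,
    seed: int = 0,
    k_folds: int = 5,
    optimizer_config: OptimizerConfig | None = None,
) -> tuple[ForestConfig, dict]:
    """Select forest hyperparameters by minimizing 1 - CV accuracy with OBL+ARA.

    ``bounds`` maps ``n_trees`` / ``max_depth`` / ``features_per_split`` to
    continuous intervals; positions are rounded to integers before
    evaluation and repeated integer configurations are memoized, so the
    costly CV objective runs once per distinct configuration.  ``budget`` is
    the number of optimizer iterations and must cover the population.
    """
    bounds = bounds or {
        "n_trees": (50, 200),
        "max_depth": (10, 40),
        "features_per_split": (2, 10),
    }
    keys = ("n_trees", "max_depth", "features_per_split")
    for key in keys:
        if key not in bounds:
            raise ValueError(f"bounds must include {key!r}")
    lo = np.array([bounds[k][0] for k in keys], dtype=float)
    hi = np.array([bounds[k][1] for k in keys], dtype=float)
    collapsed = hi - lo < 1e-9
    hi = np.where(collapsed, lo + 1e-6, hi)
    cfg = optimizer_config or OptimizerConfig(
        population=8, pool_capacity=4, n_iterations=budget, seed=seed
    )
    if budget < cfg.population:
        raise ValueError(
            f"budget {budget} is smaller than the population size {cfg.population}"
        )
    cfg = OptimizerConfig(
        population=cfg.population, pool_capacity=cfg.pool_capacity,
        beta0=cfg.beta0, max_stagnation=cfg.max_stagnation, max_flow=cfg.max_flow,
        n_iterations=budget, perturb_scale=cfg.perturb_scale,
        use_obl=cfg.use_obl, seed=seed,
    )
    y = train.labels.to_numpy()
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(train.features, y))
    cache: dict[tuple[int, int, int], float] = {}

    def objective(x):
        x = np.atleast_2d(x)
        out = np.empty(x.shape[0])
        for i, row in enumerate(x):
            key = tuple(int(round(v)) for v in row)
            if key not in cache:
                fc = ForestConfig(n_trees=max(1, key[0]), max_depth=max(1, key[1]),
                                  features_per_split=max(1, key[2]), seed=seed)
                mean_acc, _ = _cv_accuracy(train.features, y, fc, folds)
                cache[key] = 1.0 - mean_acc
            out[i] = cache[key]
        return out if out.size > 1 else float(out[0])

    trace = optimize(objective, SearchSpace(lo, hi), cfg)
    best_key = tuple(int(round(v)) for v in trace.best_position)
    best = ForestConfig(n_trees=max(1, best_key[0]), max_depth=max(1, best_key[1]),
                        features_per_split=max(1, best_key[2]), seed=seed)
    info = {
        "cv_error": float(trace.final),
        "n_distinct_configs": len(cache),
        "n_evaluations": trace.n_evaluations,
    }
    return best, info


# -- metrics ---------------------------------------------------------------


@dataclass
class MetricsReport:
    """Binary classification metrics from the confusion table."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    tp: int
    fp: int
    fn: int
    tn: int
    positive_class: object
    degenerate_precision: bool = False
    degenerate_recall: bool = False

    def as_dict(self) -> dict:
        d = asdict(self)
        d["positive_class"] = str(d["positive_class"])
        return d


def compute_metrics(y_true, y_pred, positive_class) -> MetricsReport:
    """Accuracy / precision / recall / F1 for an explicit positive class.

    Degenerate cases (no predicted positives, or no true positives in the
    sample) report 0 with a flag instead of raising.
    """
    yt = np.asarray(y_true).ravel()
    yp = np.asarray(y_pred).ravel()
    if yt.size != yp.size:
        raise ValueError("y_true and y_pred must have equal length")
    known = set(np.unique(yt)) | set(np.unique(yp))
    if positive_class not in known:
        raise ValueError(f"positive class {positive_class!r} absent from labels")
    pos_t = yt == positive_class
    pos_p = yp == positive_class
    tp = int(np.sum(pos_t & pos_p))
    fp = int(np.sum(~pos_t & pos_p))
    fn = int(np.sum(pos_t & ~pos_p))
    tn = int(np.sum(~pos_t & ~pos_p))
    accuracy = (tp + tn) / yt.size
    deg_p = (tp + fp) == 0
    deg_r = (tp + fn) == 0
    precision = 0.0 if deg_p else tp / (tp + fp)
    recall = 0.0 if deg_r else tp / (tp + fn)
    f1 = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return MetricsReport(
        accuracy=float(accuracy), precision=float(precision),
        recall=float(recall), f1=float(f1),
        tp=tp, fp=fp, fn=fn, tn=tn, positive_class=positive_class,
        degenerate_precision=deg_p, degenerate_recall=deg_r,
    )


def topk_precision(ranked_features, truth, k_cut: int) -> float:
    """Fraction of the ``k_cut`` best-ranked features that are in ``truth``."""
    ranked = list(ranked_features)
    truth = set(truth)
    if not truth:
        raise ValueError("truth set is empty")
    if k_cut < 1 or k_cut > len(ranked):
        raise ValueError(
            f"k_cut must lie in [1, {len(ranked)}], got {k_cut}"
        )
    hits = sum(1 for f in ranked[:k_cut] if f in truth)
    return hits / k_cut


# -- the full report -------------------------------------------------------


@dataclass
class EvaluationReport:
    """Importance ranking, top@k recovery and held-out metrics."""

    ranking: list[dict]
    metrics: MetricsReport
    topk: dict[int, float] | None
    top_feature_similarity: list[dict]
    seed: int | None = None

    def as_dict(self) -> dict:
        return {
            "ranking": self.ranking,
            "metrics": self.metrics.as_dict(),
            "topk": None if self.topk is None
            else {str(k): v for k, v in self.topk.items()},
            "top_feature_similarity": self.top_feature_similarity,
            "seed": self.seed,
        }

    def to_json(self) -> str:
        return json.dumps(self.as_dict(), indent=2, sort_keys=True)

    def to_text(self) -> str:
        lines = ["Feature ranking (normalized importance):"]
        for row in self.ranking:
            lines.append(
                f"  {row['rank']:>3}  {row['feature']:<24} {row['normalized_score']:.4f}"
            )
        m = self.metrics
        lines.append(
            f"Held-out metrics (positive = {m.positive_class}): "
            f"accuracy {m.accuracy:.3f}, precision {m.precision:.3f}, "
            f"recall {m.recall:.3f}, F1 {m.f1:.3f}"
        )
        if self.topk is not None:
            parts = ", ".join(f"top@{k} {v:.2f}" for k, v in sorted(self.topk.items()))
            lines.append(f"Ground-truth recovery: {parts}")
        return "\n".join(lines)


def effect_report(
    forest: WeightedRandomForestClassifier,
    test: LabeledDataset,
    truth=None,
    positive_class=None,
    k_cuts=(3, 5, 10),
    n_similar: int = 5,
    seed: int | None = None,
) -> EvaluationReport:
    """Assemble the full evaluation of a fitted forest on a held-out split.

    With ``truth`` (synthetic data) the report includes top@k precision of
    the importance ranking; without it only the ranking and the
    classification metrics are reported.  Pairwise Pearson similarity is
    computed among the ``n_similar`` top-ranked features.
    """
    frame = forest.importance_frame()
    ranking = frame.to_dict(orient="records")
    positive = positive_class if positive_class is not None else forest.classes_[0]
    y_pred = forest.predict(test.features)
    metrics = compute_metrics(test.labels.to_numpy(), y_pred, positive)
    topk = None
    if truth:
        ranked = list(frame["feature"])
        topk = {k: topk_precision(ranked, truth, k)
                for k in k_cuts if k <= len(ranked)}
    top_feats = list(frame["feature"][:n_similar])
    sims = []
    for i in range(len(top_feats)):
        for j in range(i + 1, len(top_feats)):
            rho = pearson(test.features[top_feats[i]], test.features[top_feats[j]])
            sims.append({
                "feature_a": top_feats[i],
                "feature_b": top_feats[j],
                "pearson": rho.coefficient,
            })
    return EvaluationReport(
        ranking=ranking, metrics=metrics, topk=topk,
        top_feature_similarity=sims, seed=seed,
    )
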