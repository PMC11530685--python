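"""Split-quality and feature-importance arithmetic.

This module holds the scalar mathematics behind the forest: Shannon entropy and
information gain (the split-selection criterion), the Gini index and its
before/after-split delta (the variable-importance building block), Pearson
correlation for feature-similarity reporting, and penalized-objective
evaluators (l1 / l2 / elastic-net forms).

Conventions
-----------
* Logarithms are base 2 throughout, so entropies are in bits.
* ``0 * log2(0)`` is taken to be 0.
* Ties in argmax-by-gain are broken by the lowest column index, which keeps
  every downstream construction deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SplitEvaluation",
    "CorrelationResult",
    "entropy",
    "entropy_from_counts",
    "gini_index",
    "gini_from_counts",
    "information_gain",
    "select_best_feature",
    "node_importance_delta",
    "aggregate_and_normalize_importance",
    "pearson",
    "penalized_objective",
]

_SUM_TOL = 1e-8


def _as_proportions(p, name: str = "proportions") -> np.ndarray:
    arr = np.asarray(p, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if np.any(arr < -1e-12):
        raise ValueError(f"{name} must be nonnegative, got {arr}")
    total = float(arr.sum())
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"{name} must sum to 1 within {_SUM_TOL:g}, got {total!r}")
    return np.clip(arr, 0.0, None)


def entropy(proportions) -> float:
    """Shannon entropy in bits, ``-sum p_i log2 p_i``.

    ``proportions`` must be a valid class distribution (nonnegative, summing
    to 1).  Returns 0 for a pure distribution and ``log2 K`` for the uniform
    distribution over K classes.
    """
    p = _as_proportions(proportions)
    nz = p[p > 0.0]
    return float(-np.sum(nz * np.log2(nz)))


def entropy_from_counts(counts) -> float:
    """Entropy (bits) of a class-count vector; empty/total-zero is an error."""
    c = np.asarray(counts, dtype=float).ravel()
    total = c.sum()
    if total <= 0:
        raise ValueError("counts must contain at least one sample")
    return entropy(c / total)


def gini_index(proportions) -> float:
    """Gini impurity ``1 - sum p_k^2``; 0 iff pure, 1 - 1/K at uniform."""
    p = _as_proportions(proportions)
    return float(1.0 - np.sum(p * p))


def gini_from_counts(counts) -> float:
    c = np.asarray(counts, dtype=float).ravel()
    total = c.sum()
    if total <= 0:
        raise ValueError("counts must contain at least one sample")
    return gini_index(c / total)


@dataclass(frozen=True)
class SplitEvaluation:
    """Information-gain bookkeeping for one candidate feature.

    ``gain = parent_entropy - conditional_entropy``, all in bits.
    """

    feature: object
    parent_entropy: float
    conditional_entropy: float
    gain: float


def information_gain(labels, feature, feature_id=None) -> SplitEvaluation:
    """Information gain of a discrete-valued feature for a label vector.

    gain = Ent(labels) - sum_v (n_v / n) * Ent(labels | feature == v)
    """
    y = np.asarray(labels).ravel()
    x = np.asarray(feature).ravel()
    if y.size == 0:
        raise ValueError("labels must be non-empty")
    if y.size != x.size:
        raise ValueError(f"labels ({y.size}) and feature ({x.size}) lengths differ")
    n = y.size
    _, y_codes = np.unique(y, return_inverse=True)
    values, x_codes = np.unique(x, return_inverse=True)
    parent = entropy_from_counts(np.bincount(y_codes))
    conditional = 0.0
    for v in range(values.size):
        mask = x_codes == v
        nv = int(mask.sum())
        conditional += (nv / n) * entropy_from_counts(np.bincount(y_codes[mask]))
    gain = parent - conditional
    if gain < 0.0:  # numerical fuzz only; gain is mathematically >= 0
        gain = 0.0
    return SplitEvaluation(
        feature=feature_id,
        parent_entropy=parent,
        conditional_entropy=conditional,
        gain=gain,
    )


def select_best_feature(labels, features, names=None):
    """Argmax-gain feature among candidate columns.

    ``features`` is an (n_samples, n_features) array of discrete values (or a
    sequence of columns).  Ties are broken by the lowest column index; if
    ``names`` is given the winning name is returned instead of the index.
    """
    cols = np.atleast_2d(np.asarray(features))
    if cols.shape[0] == np.asarray(labels).ravel().size and cols.ndim == 2:
        columns = [cols[:, j] for j in range(cols.shape[1])]
    else:  # sequence of columns
        columns = [np.asarray(c).ravel() for c in features]
    if not columns:
        raise ValueError("need at least one candidate feature")
    gains = [information_gain(labels, c).gain for c in columns]
    best = int(np.argmax(gains))  # argmax returns the first (lowest) index on ties
    return names[best] if names is not None else best


def node_importance_delta(
    parent_counts,
    left_counts,
    right_counts,
    *,
    weighted: bool = False,
) -> float:
    """Gini change of one split: ``Gini_m - Gini_l - Gini_r``.

    The default is the plain unweighted difference of the three node Gini
    indices.  Because the children are not weighted by their sample shares
    this quantity can be negative (two children nearly as impure as the
    parent sum to almost twice its Gini).  ``weighted=True`` switches to the
    child-share-weighted decrease ``Gini_m - (n_l/n) Gini_l - (n_r/n) Gini_r``,
    which is always nonnegative.
    """
    p = np.asarray(parent_counts, dtype=float).ravel()
    l = np.asarray(left_counts, dtype=float).ravel()
    r = np.asarray(right_counts, dtype=float).ravel()
    if p.shape != l.shape or p.shape != r.shape:
        raise ValueError("parent/left/right count vectors must share a shape")
    if not np.allclose(l + r, p, rtol=0.0, atol=1e-9):
        raise ValueError("left and right counts must partition the parent counts")
    g_p = gini_from_counts(p)
    g_l = gini_from_counts(l)
    g_r = gini_from_counts(r)
    if weighted:
        n = p.sum()
        return float(g_p - (l.sum() / n) * g_l - (r.sum() / n) * g_r)
    return float(g_p - g_l - g_r)


def aggregate_and_normalize_importance(per_tree_scores, n_features=None) -> np.ndarray:
    """Sum per-tree, per-feature importance scores and normalize to sum 1.

    ``per_tree_scores`` is an iterable of length-d arrays (one per tree; each
    entry already sums that tree's per-node deltas for the feature).  Raw
    scores are clipped at zero before normalizing so that the result is a
    proper distribution even when as-printed node deltas went negative.  A
    forest with no splits at all yields uniform scores with a warning.
    """
    mats = [np.asarray(v, dtype=float).ravel() for v in per_tree_scores]
    if not mats:
        raise ValueError("need at least one tree's scores")
    d = n_features if n_features is not None else mats[0].size
    raw = np.zeros(d)
    for v in mats:
        if v.size != d:
            raise ValueError("per-tree score vectors must share a length")
        raw += v
    clipped = np.clip(raw, 0.0, None)
    total = clipped.sum()
    if total <= 0.0:
        warnings.warn(
            "forest contributed no positive importance (no splits?); "
            "returning uniform scores",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.full(d, 1.0 / d)
    return clipped / total


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation with its covariance/SD ingredients."""

    covariance: float
    std_x: float
    std_y: float
    coefficient: float


def pearson(x, y) -> CorrelationResult:
    """Pearson correlation ``cov(x, y) / (sigma_x sigma_y)``.

    Population (ddof=0) moments; both inputs need length >= 2 and nonzero
    variance, otherwise the correlation is undefined and a ValueError is
    raised.
    """
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if xv.size != yv.size:
        raise ValueError("x and y must have equal length")
    if xv.size < 2:
        raise ValueError("need at least two points")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    sx = float(np.sqrt(np.mean(xc * xc)))
    sy = float(np.sqrt(np.mean(yc * yc)))
    if sx == 0.0 or sy == 0.0:
        raise ValueError("correlation undefined: zero variance input")
    cov = float(np.mean(xc * yc))
    rho = cov / (sx * sy)
    rho = min(1.0, max(-1.0, rho))
    return CorrelationResult(covariance=cov, std_x=sx, std_y=sy, coefficient=rho)


_VARIANTS = ("l1", "l2", "elastic", "elastic_standard")


def penalized_objective(risk: float, w, *, alpha: float = 0.0, lam: float = 0.0,
                        variant: str = "l1") -> float:
    """Penalized objective value for a weight vector.

    variant:
      * ``"l1"``:      J + lam * ||w||_1
      * ``"l2"``:      J + alpha * ||w||_2            (the 2-norm itself)
      * ``"elastic"``: J + alpha*lam*||w||_1 + ((1-alpha)/2)*alpha*||w||_2
      * ``"elastic_standard"``: J + lam*(alpha*||w||_1 + ((1-alpha)/2)*||w||_2^2)

    The ``"elastic"`` form repeats the alpha factor on both terms; the
    conventional mixture is available as ``"elastic_standard"``.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"unknown variant {variant!r}; expected one of {_VARIANTS}")
    if alpha < 0 or lam < 0:
        raise ValueError("alpha and lam must be nonnegative")
    wv = np.asarray(w, dtype=float).ravel()
    l1 = float(np.sum(np.abs(wv)))
    l2 = float(np.sqrt(np.sum(wv * wv)))
    if variant == "l1":
        return float(risk + lam * l1)
    if variant == "l2":
        return float(risk + alpha * l2)
    if variant == "elastic":
        return float(risk + alpha * lam * l1 + 0.5 * (1.0 - alpha) * alpha * l2)
    return float(risk + lam * (alpha * l1 + 0.5 * (1.0 - alpha) * l2 * l2))
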