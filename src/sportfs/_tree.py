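"""Compiled kernels for growing and applying information-gain trees.

The grower is an explicit-stack CART-style builder: at each node it samples
``mtry`` candidate features without replacement, scans midpoint thresholds in
sorted order, and keeps the split with the highest information gain
(entropy, base 2).  Ties go to the lowest column index because candidates
are examined in ascending order with a strict improvement test.  A node
becomes a leaf on purity, depth limit, minimum leaf size, or when no
candidate offers positive gain.

Two per-feature importance accumulators are filled while growing:

* ``vim_printed`` — the plain unweighted Gini delta of each split,
  ``Gini_m - Gini_l - Gini_r``;
* ``vim_mdi``     — the standard mean-decrease-impurity contribution,
  ``(m/n) * (Gini_m - (n_l/m) Gini_l - (n_r/m) Gini_r)``.

``X`` is passed transposed (features by samples, C order) so per-feature
gathers stay within one cache-friendly row.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_EPS = 1e-12


@njit(cache=True)
def _entropy_counts(counts, total):
    h = 0.0
    for k in range(counts.shape[0]):
        c = counts[k]
        if c > 0.0:
            p = c / total
            h -= p * np.log2(p)
    return h


@njit(cache=True)
def _gini_counts(counts, total):
    s = 0.0
    for k in range(counts.shape[0]):
        p = counts[k] / total
        s += p * p
    return 1.0 - s


@njit(cache=True)
def grow_tree(XT, y, n_classes, max_depth, mtry, min_samples_leaf, seed, sample_idx):
    """Grow one tree on columns ``sample_idx`` of ``XT`` (features x samples).

    Returns (feature, threshold, left, right, value, node_gini, n_nodes,
    vim_printed, vim_mdi).  ``feature[i] == -1`` marks a leaf; ``value`` holds
    per-node class counts of the in-bag samples reaching the node.
    """
    n_total = sample_idx.shape[0]
    d = XT.shape[0]
    max_nodes = 2 * n_total + 1
    feature = np.full(max_nodes, -1, np.int64)
    threshold = np.zeros(max_nodes)
    left = np.full(max_nodes, -1, np.int64)
    right = np.full(max_nodes, -1, np.int64)
    value = np.zeros((max_nodes, n_classes))
    node_gini = np.zeros(max_nodes)
    vim_printed = np.zeros(d)
    vim_mdi = np.zeros(d)

    idx = sample_idx.copy()
    np.random.seed(seed)

    stack = np.empty((max_nodes, 4), np.int64)  # node, start, end, depth
    stack[0, 0] = 0
    stack[0, 1] = 0
    stack[0, 2] = n_total
    stack[0, 3] = 0
    sp = 1
    n_nodes = 1

    feat_buf = np.empty(d, np.int64)
    counts = np.empty(n_classes)
    left_counts = np.empty(n_classes)
    best_left_counts = np.empty(n_classes)
    vals = np.empty(n_total)
    ybuf = np.empty(n_total, np.int64)
    svals = np.empty(n_total)
    slabs = np.empty(n_total, np.int64)

    while sp > 0:
        sp -= 1
        node = stack[sp, 0]
        start = stack[sp, 1]
        end = stack[sp, 2]
        depth = stack[sp, 3]
        m = end - start

        for k in range(n_classes):
            counts[k] = 0.0
        for i in range(m):
            ybuf[i] = y[idx[start + i]]
            counts[ybuf[i]] += 1.0
        for k in range(n_classes):
            value[node, k] = counts[k]
        g_parent = _gini_counts(counts, m)
        node_gini[node] = g_parent

        pure = False
        for k in range(n_classes):
            if counts[k] == m:
                pure = True
        if pure or depth >= max_depth or m < 2 * min_samples_leaf or m < 2:
            continue

        h_parent = _entropy_counts(counts, m)

        # sample mtry candidate features without replacement (partial Fisher-Yates)
        for j in range(d):
            feat_buf[j] = j
        k_feats = mtry if mtry < d else d
        for j in range(k_feats):
            r = j + np.random.randint(0, d - j)
            tmp = feat_buf[j]
            feat_buf[j] = feat_buf[r]
            feat_buf[r] = tmp
        chosen = np.sort(feat_buf[:k_feats])

        best_gain = 0.0
        best_f = -1
        best_thr = 0.0

        for fi in range(k_feats):
            f = chosen[fi]
            for i in range(m):
                vals[i] = XT[f, idx[start + i]]
            order = np.argsort(vals[:m])
            for i in range(m):
                svals[i] = vals[order[i]]
                slabs[i] = ybuf[order[i]]
            for k in range(n_classes):
                left_counts[k] = 0.0
            for pos in range(m - 1):
                left_counts[slabs[pos]] += 1.0
                if svals[pos + 1] <= svals[pos]:
                    continue
                nl = pos + 1
                nr = m - nl
                if nl < min_samples_leaf or nr < min_samples_leaf:
                    continue
                h_l = _entropy_counts(left_counts, nl)
                h_r = 0.0
                for k in range(n_classes):
                    c = counts[k] - left_counts[k]
                    if c > 0.0:
                        p = c / nr
                        h_r -= p * np.log2(p)
                gain = h_parent - (nl / m) * h_l - (nr / m) * h_r
                if gain > best_gain + _EPS:
                    best_gain = gain
                    best_f = f
                    best_thr = 0.5 * (svals[pos] + svals[pos + 1])
                seen_change = False

        if best_f < 0 or best_gain <= _EPS:
            continue  # no useful split on the sampled candidates -> leaf

        # stable partition of idx[start:end] by the chosen threshold
        buf = np.empty(m, np.int64)
        nl = 0
        nr = 0
        for k in range(n_classes):
            best_left_counts[k] = 0.0
        for i in range(start, end):
            if XT[best_f, idx[i]] <= best_thr:
                idx[start + nl] = idx[i]
                best_left_counts[y[idx[i]]] += 1.0
                nl += 1
            else:
                buf[nr] = idx[i]
                nr += 1
        for i in range(nr):
            idx[start + nl + i] = buf[i]

        g_l = _gini_counts(best_left_counts, nl)
        for k in range(n_classes):
            left_counts[k] = counts[k] - best_left_counts[k]
        g_r = _gini_counts(left_counts, nr)
        vim_printed[best_f] += g_parent - g_l - g_r
        vim_mdi[best_f] += (m / n_total) * (
            g_parent - (nl / m) * g_l - (nr / m) * g_r
        )

        feature[node] = best_f
        threshold[node] = best_thr
        lid = n_nodes
        rid = n_nodes + 1
        n_nodes += 2
        left[node] = lid
        right[node] = rid
        stack[sp, 0] = rid
        stack[sp, 1] = start + nl
        stack[sp, 2] = end
        stack[sp, 3] = depth + 1
        sp += 1
        stack[sp, 0] = lid
        stack[sp, 1] = start
        stack[sp, 2] = start + nl
        stack[sp, 3] = depth + 1
        sp += 1

    return (
        feature[:n_nodes],
        threshold[:n_nodes],
        left[:n_nodes],
        right[:n_nodes],
        value[:n_nodes],
        node_gini[:n_nodes],
        n_nodes,
        vim_printed,
        vim_mdi,
    )


@njit(cache=True)
def apply_tree(feature, threshold, left, right, X):
    """Leaf index for every row of ``X`` (samples x features)."""
    n = X.shape[0]
    out = np.empty(n, np.int64)
    for i in range(n):
        node = 0
        while feature[node] >= 0:
            if X[i, feature[node]] <= threshold[node]:
                node = left[node]
            else:
                node = right[node]
        out[i] = node
    return out
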