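"""Brute-force reference tree for equivalence checks.

Independent of the package implementation: recursive exhaustive search over
binary feature splits using a contingency-table information gain, with the
same documented conventions (lowest-index tie-break, leaf on zero gain,
majority prediction with lowest-class-index ties).
"""

import math


def _entropy(labels):
    n = len(labels)
    h = 0.0
    for c in set(labels):
        p = labels.count(c) / n
        h -= p * math.log2(p)
    return h


def _gain(labels, column):
    n = len(labels)
    parent = _entropy(labels)
    conditional = 0.0
    for v in set(column):
        sub = [l for l, x in zip(labels, column) if x == v]
        conditional += (len(sub) / n) * _entropy(sub)
    return parent - conditional


def _majority(labels):
    classes = sorted(set(labels))
    return max(classes, key=lambda c: (labels.count(c), -classes.index(c)))


def oracle_predict(X, y):
    """Predictions of the exhaustive-search tree on its own training rows.

    ``X`` is a list of binary (0/1) feature rows, ``y`` a list of class
    labels.  All features are candidates at every node; no depth limit.
    """
    d = len(X[0]) if X else 0

    def build(rows):
        labels = [y[i] for i in rows]
        if len(set(labels)) == 1:
            cls = labels[0]
            return lambda row: cls
        gains = [_gain(labels, [X[i][j] for i in rows]) for j in range(d)]
        best = 0
        for j in range(1, d):
            if gains[j] > gains[best] + 1e-12:
                best = j
        if gains[best] <= 1e-12:
            cls = _majority(labels)
            return lambda row: cls
        left_rows = [i for i in rows if X[i][best] == 0]
        right_rows = [i for i in rows if X[i][best] == 1]
        left = build(left_rows)
        right = build(right_rows)
        j = best
        return lambda row: left(row) if row[j] == 0 else right(row)

    tree = build(list(range(len(y))))
    return [tree(row) for row in X]
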