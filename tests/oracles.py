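"""Independent brute-force oracles used to cross-check the package.

Everything here is written as plain loops over matrix entries, deliberately
ignoring the vectorised implementations under test.
"""

from __future__ import annotations

import math

import numpy as np


def brute_confusion(score_mat, label_mat, excluded, threshold):
    """Count tp/fp/tn/fn by explicit double loop over the upper triangle."""
    L = score_mat.shape[0]
    tp = fp = tn = fn = 0
    for i in range(L):
        for j in range(i + 1, L):
            if excluded[i, j]:
                continue
            pred = score_mat[i, j] >= threshold
            true = bool(label_mat[i, j])
            if pred and true:
                tp += 1
            elif pred and not true:
                fp += 1
            elif not pred and true:
                fn += 1
            else:
                tn += 1
    return tp, fp, tn, fn


def brute_derived(tp, fp, tn, fn):
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    d = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(d) if d else 0.0
    return precision, recall, f1, mcc


def brute_top_kl(score_mat, label_mat, excluded, k, L):
    """Rank included pairs by (score desc, i, j) with an explicit sort."""
    pairs = []
    n = score_mat.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if not excluded[i, j]:
                pairs.append((-score_mat[i, j], i, j))
    pairs.sort()
    m = math.ceil(k * L)
    top = pairs[:m]
    return sum(label_mat[i, j] for _, i, j in top) / m


def brute_pairwise_identity_weights(rows, threshold):
    """DCA reweighting oracle: all-pairs fractional identity, python loops."""
    E = len(rows)
    weights = []
    for i in range(E):
        count = 0
        for j in range(E):
            ident = sum(a == b for a, b in zip(rows[i], rows[j])) / len(rows[i])
            if ident >= threshold:
                count += 1
        weights.append(1.0 / count)
    return np.array(weights)


def brute_min_distance(coords_a, coords_b):
    best = float("inf")
    for a in coords_a:
        for b in coords_b:
            d = math.dist(a, b)
            best = min(best, d)
    return best
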