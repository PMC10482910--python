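"""Contact-prediction evaluation.

Predictions are symmetric real-valued score matrices; ground truth is a
symmetric binary matrix with a minimum-separation exclusion.  Every metric
operates on the included upper-triangle pairs only.  Two aggregation
conventions are supported: *micro* pools confusion counts over samples before
deriving a metric; *macro* derives the metric per sample and averages
(reporting the standard deviation as dispersion).

Top-(k·L) precision ranks all included pairs by score, treats the ⌈k·L⌉
highest as positive predictions and reports the fraction that are true
contacts; ties are broken lexicographically on (i, j) so results are
deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .structure import ContactLabels, separation_mask

__all__ = [
    "ContactScores",
    "ConfusionCounts",
    "confusion_counts",
    "derived_metrics",
    "top_kl_precision",
    "aggregate",
    "precision_curve",
    "evaluation_report",
]


@dataclass
class ContactScores:
    """Symmetric real-valued contact scores with an exclusion mask."""

    matrix: np.ndarray
    min_separation: int = 4
    excluded_mask: np.ndarray = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        L = self.matrix.shape[0]
        if self.matrix.shape != (L, L):
            raise ValueError("score matrix must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=0.0):
            raise ValueError("score matrix must be symmetric")
        sep = separation_mask(L, self.min_separation)
        if self.excluded_mask is None:
            self.excluded_mask = sep
        else:
            self.excluded_mask = np.asarray(self.excluded_mask, dtype=bool) | sep

    @property
    def L(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    scope: str = "per-sample"

    @property
    def n_pairs(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn, "pooled")


def _included_upper(scores: ContactScores, labels: ContactLabels):
    if scores.L != labels.L:
        raise ValueError(f"score size {scores.L} != label size {labels.L}")
    L = labels.L
    iu, ju = np.triu_indices(L, k=1)
    keep = ~(scores.excluded_mask[iu, ju] | labels.excluded_mask[iu, ju])
    return iu[keep], ju[keep]


def confusion_counts(scores: ContactScores, labels: ContactLabels,
                     threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts over included upper-triangle pairs.

    A pair is predicted positive iff its score is >= ``threshold``."""
    iu, ju = _included_upper(scores, labels)
    pred = scores.matrix[iu, ju] >= threshold
    true = labels.matrix[iu, ju].astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(pred & true)),
        fp=int(np.sum(pred & ~true)),
        tn=int(np.sum(~pred & ~true)),
        fn=int(np.sum(~pred & true)),
    )


def derived_metrics(c: ConfusionCounts) -> dict:
    """Precision, recall, F1 and the (signed) Matthews correlation.

    Any metric whose denominator contains a zero factor is defined as 0."""
    tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return {"precision": precision, "recall": recall, "F1": f1, "MCC": mcc}


def _ranked_pairs(scores: ContactScores, labels: ContactLabels):
    iu, ju = _included_upper(scores, labels)
    s = scores.matrix[iu, ju]
    order = np.lexsort((ju, iu, -s))  # descending score, then (i, j) lexicographic
    return iu[order], ju[order]


def top_kl_precision(scores: ContactScores, labels: ContactLabels,
                     k: float = 1.0, L: int | None = None) -> float:
    """Precision over the ⌈k·L⌉ highest-scoring included pairs.

    ``L`` defaults to the matrix size; pass the query's ungapped length when
    the matrix spans alignment columns with query gaps."""
    if k <= 0:
        raise ValueError("k must be positive")
    L = labels.L if L is None else int(L)
    n = math.ceil(k * L)
    iu, ju = _ranked_pairs(scores, labels)
    if n > len(iu):
        raise ValueError(f"top-{n} requested but only {len(iu)} included pairs exist")
    sel_i, sel_j = iu[:n], ju[:n]
    return float(labels.matrix[sel_i, sel_j].sum() / n)


def aggregate(values_or_counts, mode: str):
    """Aggregate per-sample results.

    * ``micro``: expects :class:`ConfusionCounts`; pools them and derives the
      metrics once.
    * ``macro``: derives per sample then averages; returns ``(mean, std)``
      per metric (population std).  Plain scalars are averaged directly.
    """
    items = list(values_or_counts)
    if not items:
        raise ValueError("need at least one sample")
    if mode == "micro":
        if not isinstance(items[0], ConfusionCounts):
            raise ValueError("micro aggregation requires confusion counts")
        pooled = items[0]
        for c in items[1:]:
            pooled = pooled + c
        return derived_metrics(pooled)
    if mode != "macro":
        raise ValueError("mode must be 'micro' or 'macro'")
    if isinstance(items[0], ConfusionCounts):
        per = [derived_metrics(c) for c in items]
        return {
            name: (float(np.mean([p[name] for p in per])),
                   float(np.std([p[name] for p in per])))
            for name in per[0]
        }
    arr = np.asarray(items, dtype=float)
    return (float(arr.mean()), float(arr.std()))


def precision_curve(scores_list, labels_list, k_grid, L_list=None) -> dict:
    """Top-(k·L) precision per sample and its mean ± std across samples.

    Returns ``{"k": array, "per_sample": (n_samples, n_k), "mean": array,
    "std": array}``, ready for export or plotting."""
    k_grid = np.asarray(list(k_grid), dtype=float)
    if np.any(np.diff(k_grid) <= 0):
        raise ValueError("k_grid must be strictly increasing")
    if L_list is None:
        L_list = [None] * len(scores_list)
    per = np.array([
        [top_kl_precision(s, lab, k, L) for k in k_grid]
        for s, lab, L in zip(scores_list, labels_list, L_list)
    ])
    return {"k": k_grid, "per_sample": per,
            "mean": per.mean(axis=0), "std": per.std(axis=0)}


def evaluation_report(family_ids, scores_list, labels_list,
                      threshold: float = 0.5, L_list=None) -> pd.DataFrame:
    """Per-family table (top-L PPV, MCC, P/R/F1) plus a pooled (micro) row."""
    if L_list is None:
        L_list = [lab.L for lab in labels_list]
    rows, counts = [], []
    for fam, s, lab, L in zip(family_ids, scores_list, labels_list, L_list):
        c = confusion_counts(s, lab, threshold)
        counts.append(c)
        d = derived_metrics(c)
        rows.append({
            "family": fam, "L": L,
            "top_L_precision": top_kl_precision(s, lab, 1.0, L),
            "MCC": d["MCC"], "precision": d["precision"],
            "recall": d["recall"], "F1": d["F1"],
        })
    pooled = aggregate(counts, "micro")
    rows.append({
        "family": "POOLED", "L": int(np.sum(L_list)),
        "top_L_precision": float(np.mean([r["top_L_precision"] for r in rows])),
        "MCC": pooled["MCC"], "precision": pooled["precision"],
        "recall": pooled["recall"], "F1": pooled["F1"],
    })
    return pd.DataFrame(rows)
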