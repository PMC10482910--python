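"""Downstream contact heads on attention-map pair features.

The input of a downstream model is the per-pair feature vector collecting,
for alignment pair (i, j), the pre-softmax tied row-attention logits of every
head in every block (N·H channels, symmetrised by averaging the (i, j) and
(j, i) entries).  Two heads map these features to contact log-odds:

* :class:`LogisticContactHead` — bias-free logistic regression: the log-odds
  are a pure weighted sum of attention values (no intercept), so a zero
  feature vector always maps to probability 0.5;
* :class:`BoostedContactEnsemble` — a gradient-boosted CART ensemble
  f(x) = w_q(x) per tree; the ensemble margin F_K(x) = Σ_k f_k(x) is read as
  log-odds.  Fitting delegates to xgboost, but scoring re-evaluates the
  exported trees with this module's own sum-of-leaf-scores formula.

Three regimes are supported: frozen backbone (head only), fine-tuned
(logistic head trained jointly with the backbone), and fine-tuned + boosted
(trees fit on features of a fine-tuned checkpoint).  Early stopping uses a
family-level holdout and records a checkpoint at the best value of every
configured metric.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import xgboost as xgb
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .backbone import AttentionMaps, AxialBackbone
from .metrics import (ConfusionCounts, ContactScores, confusion_counts,
                      derived_metrics, top_kl_precision)
from .msa import TokenGrid
from .structure import ContactLabels

__all__ = [
    "PairFeatureTable",
    "LabeledFamily",
    "EarlyStopPlan",
    "extract_pair_features",
    "pairs_to_scores",
    "LogisticContactHead",
    "BoostedContactEnsemble",
    "ensemble_score",
    "fit_logistic",
    "fit_boosted",
    "finetune_then_boost",
    "predict_contacts",
    "save_model",
    "load_model",
]

EARLY_STOP_METRICS = ("loss", "MCC", "F1", "top_l")


@dataclass
class PairFeatureTable:
    """Per-pair feature rows for the downstream heads."""

    pairs: np.ndarray                      # (P, 2) int, i < j
    X: np.ndarray                          # (P, n_channels)
    y: np.ndarray | None = None            # (P,) binary
    family_ids: np.ndarray | None = None   # (P,) str
    L_by_family: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pairs = np.asarray(self.pairs, dtype=np.int64)
        self.X = np.asarray(self.X, dtype=float)
        if self.pairs.shape[0] != self.X.shape[0]:
            raise ValueError("pairs and features must have equal row counts")

    @property
    def n_features(self) -> int:
        return self.X.shape[1]


@dataclass
class LabeledFamily:
    """A tokenized family with its contact labels (downstream sample)."""

    grid: TokenGrid
    labels: ContactLabels
    family_id: str


@dataclass
class EarlyStopPlan:
    """Which metrics to monitor, for how long, and on which holdout families."""

    metrics: tuple = ("loss",)
    patience: int = 10
    holdout: tuple = ()

    def __post_init__(self):
        self.metrics = tuple(self.metrics)
        self.holdout = tuple(self.holdout)
        for m in self.metrics:
            if m not in EARLY_STOP_METRICS:
                raise ValueError(f"unknown early-stop metric {m!r}")


def split_holdout(families, holdout_fraction: float = 0.1, seed: int = 0):
    """Family-id-level holdout split (at least one holdout family)."""
    fams = sorted({f.family_id for f in families})
    rng = np.random.default_rng(seed)
    n_hold = max(1, int(round(holdout_fraction * len(fams))))
    hold = set(rng.choice(fams, size=n_hold, replace=False).tolist())
    return tuple(sorted(hold))


def included_pairs(L: int, min_separation: int) -> np.ndarray:
    iu, ju = np.triu_indices(L, k=1)
    keep = (ju - iu) >= min_separation
    return np.stack([iu[keep], ju[keep]], axis=1)


def extract_pair_features(maps: AttentionMaps, min_separation: int = 4,
                          labels: ContactLabels | None = None,
                          family_id: str = "") -> PairFeatureTable:
    """Symmetrised attention-pixel features for all included pairs.

    Channel c of pair (i, j) is (maps[c][i, j] + maps[c][j, i]) / 2."""
    L = maps.maps.shape[1]
    pairs = included_pairs(L, min_separation)
    iu, ju = pairs[:, 0], pairs[:, 1]
    X = 0.5 * (maps.maps[:, iu, ju] + maps.maps[:, ju, iu]).T
    y = None
    if labels is not None:
        if labels.L != L:
            raise ValueError("label size does not match attention maps")
        keep = ~labels.excluded_mask[iu, ju]
        pairs, X = pairs[keep], X[keep]
        y = labels.matrix[pairs[:, 0], pairs[:, 1]].astype(np.int64)
    fam = np.full(len(pairs), family_id) if family_id else None
    table = PairFeatureTable(pairs, X, y, fam)
    if family_id:
        table.L_by_family[family_id] = L
    return table


def concat_tables(tables) -> PairFeatureTable:
    out = PairFeatureTable(
        np.concatenate([t.pairs for t in tables]),
        np.concatenate([t.X for t in tables]),
        None if tables[0].y is None else np.concatenate([t.y for t in tables]),
        None if tables[0].family_ids is None else np.concatenate([t.family_ids for t in tables]),
    )
    for t in tables:
        out.L_by_family.update(t.L_by_family)
    return out


def pairs_to_scores(pairs: np.ndarray, probs: np.ndarray, L: int,
                    min_separation: int = 4) -> ContactScores:
    """Assemble a symmetric score matrix from per-pair probabilities."""
    m = np.zeros((L, L))
    m[pairs[:, 0], pairs[:, 1]] = probs
    m[pairs[:, 1], pairs[:, 0]] = probs
    return ContactScores(m, min_separation)


# ---------------------------------------------------------------------------
# differentiable losses over probabilities


def _sample_weights(y: np.ndarray, balanced: bool) -> np.ndarray:
    w = np.ones(len(y))
    if balanced:
        pos = y.sum()
        neg = len(y) - pos
        if pos > 0:
            w[y == 1] = neg / pos
    return w


def pair_loss(p: nn.Tensor, y: np.ndarray, kind: str, balanced: bool = True,
              focal_gamma: float = 2.0, dice_smooth: float = 1.0) -> nn.Tensor:
    """Contact losses: weighted cross-entropy, focal (γ=2) or dice."""
    y = np.asarray(y, dtype=float)
    eps = 1e-12
    if kind == "dice":
        num = (p * nn.Tensor(y)).sum() * 2.0 + dice_smooth
        den = p.sum() + y.sum() + dice_smooth
        return 1.0 - num / den
    w = nn.Tensor(_sample_weights(y.astype(int), balanced))
    yt = nn.Tensor(y)
    ce = -(yt * (p + eps).log() + (1.0 - yt) * (1.0 - p + eps).log())
    if kind == "cross-entropy":
        return (w * ce).sum() / w.sum()
    if kind == "focal":
        pt = yt * p + (1.0 - yt) * (1.0 - p)
        return (w * (1.0 - pt) ** focal_gamma * ce).sum() / w.sum()
    raise ValueError(f"unknown loss kind {kind!r}")


# ---------------------------------------------------------------------------
# logistic head


class LogisticContactHead(BaseEstimator, ClassifierMixin):
    """Bias-free logistic regression on attention-pixel features.

    The contact log-odds are ``w·x`` with no intercept, so the decision
    threshold 0.5 corresponds exactly to log-odds 0 and a zero feature
    vector yields probability 0.5.

    Parameters
    ----------
    loss : {"cross-entropy", "focal", "dice"}
    balanced : bool
        Weight positive pairs by #neg/#pos (contacts are sparse).
    learning_rate, max_epochs, seed : optimisation controls (full-batch Adam).
    """

    def __init__(self, loss: str = "cross-entropy", balanced: bool = True,
                 learning_rate: float = 0.05, max_epochs: int = 300,
                 focal_gamma: float = 2.0, dice_smooth: float = 1.0,
                 seed: int = 0):
        self.loss = loss
        self.balanced = balanced
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.focal_gamma = focal_gamma
        self.dice_smooth = dice_smooth
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        rng = np.random.default_rng(self.seed)
        w = nn.Parameter(rng.normal(0.0, 0.01, size=X.shape[1]))
        opt = nn.Adam([w], lr=self.learning_rate)
        Xt = nn.Tensor(X)
        for _ in range(self.max_epochs):
            opt.zero_grad()
            p = (Xt @ w).sigmoid()
            loss = pair_loss(p, y, self.loss, self.balanced,
                             self.focal_gamma, self.dice_smooth)
            loss.backward()
            opt.step()
        self.coef_ = w.data.copy()
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def decision_function(self, X):
        return np.asarray(X, dtype=float) @ self.coef_

    def predict_proba(self, X):
        z = self.decision_function(X)
        p = 1.0 / (1.0 + np.exp(-z))
        return np.stack([1.0 - p, p], axis=1)

    def predict(self, X):
        return (self.decision_function(X) >= 0.0).astype(int)


# ---------------------------------------------------------------------------
# boosted CART ensemble


def _parse_dump(booster: xgb.Booster) -> list:
    return [json.loads(t) for t in booster.get_dump(dump_format="json")]


def _eval_tree(node: dict, X32: np.ndarray) -> np.ndarray:
    """Route every row to its leaf and return the leaf scores (w_q(x))."""
    out = np.empty(X32.shape[0])
    stack = [(node, np.arange(X32.shape[0]))]
    while stack:
        nd, idx = stack.pop()
        if "leaf" in nd:
            out[idx] = nd["leaf"]
            continue
        feat = int(nd["split"].lstrip("f"))
        thr = np.float32(nd["split_condition"])
        children = {c["nodeid"]: c for c in nd["children"]}
        go_yes = X32[idx, feat] < thr
        stack.append((children[nd["yes"]], idx[go_yes]))
        stack.append((children[nd["no"]], idx[~go_yes]))
    return out


def ensemble_score(trees, X):
    """Sum-of-leaf-scores evaluation: F_K(x) = Σ_k w_{q_k(x)}.

    ``trees`` may be a parsed tree list or a fitted
    :class:`BoostedContactEnsemble`.  Returns ``(log_odds, probability)``;
    an empty ensemble scores log-odds 0 (probability 0.5)."""
    if isinstance(trees, BoostedContactEnsemble):
        trees = trees.trees_
    X32 = np.asarray(X, dtype=np.float32).astype(np.float32)
    if X32.ndim == 1:
        X32 = X32[None, :]
    margin = np.zeros(X32.shape[0])
    for t in trees:
        margin += _eval_tree(t, X32)
    prob = 1.0 / (1.0 + np.exp(-margin))
    return margin, prob


def _focal_objective(gamma: float, w_pos: float):
    """Gradient/hessian of the class-weighted focal loss for xgboost."""

    def obj(preds, dtrain):
        y = dtrain.get_label()
        p = 1.0 / (1.0 + np.exp(-preds))
        w = np.where(y == 1, w_pos, 1.0)
        eps = 1e-12
        pt = np.where(y == 1, p, 1 - p)
        # loss = w (1-pt)^g (-log pt); chain rule through pt = sigmoid(±z)
        dloss_dpt = -gamma * (1 - pt) ** (gamma - 1) * (-np.log(pt + eps)) \
            - (1 - pt) ** gamma / (pt + eps)
        dpt_dz = np.where(y == 1, p * (1 - p), -p * (1 - p))
        grad = w * dloss_dpt * dpt_dz
        hess = np.maximum(w * p * (1 - p), 1e-6)  # Gauss-Newton surrogate
        return grad, hess

    return obj


class BoostedContactEnsemble(BaseEstimator, ClassifierMixin):
    """Gradient-boosted CART ensemble over pair features.

    Fitting delegates to xgboost (exact greedy trees, single thread for
    reproducibility); the fitted model is exported to plain trees
    (``trees_``) and all scoring goes through :func:`ensemble_score`, i.e.
    the explicit sum of leaf scores interpreted as log-odds.

    Early stopping (optional ``eval_set``) scans cumulative per-tree margins
    on the holdout and truncates the ensemble at the best round of
    ``eval_metric`` with the configured patience.
    """

    def __init__(self, n_rounds: int = 200, max_depth: int = 3,
                 learning_rate: float = 0.1, loss: str = "cross-entropy",
                 balanced: bool = True, focal_gamma: float = 2.0,
                 reg_lambda: float = 1.0, patience: int = 10, seed: int = 0):
        self.n_rounds = n_rounds
        self.max_depth = max_depth
        self.learning_rate = learning_rate
        self.loss = loss
        self.balanced = balanced
        self.focal_gamma = focal_gamma
        self.reg_lambda = reg_lambda
        self.patience = patience
        self.seed = seed

    def fit(self, X, y, eval_set=None, eval_metric="loss", eval_context=None):
        """Fit on features/labels; optional ``eval_set=(X_val, y_val)``.

        ``eval_metric`` is one of loss/MCC/F1/top_l; ``top_l`` additionally
        needs ``eval_context=(pairs_val, family_ids_val, L_by_family)``."""
        if self.n_rounds < 1:
            raise ValueError("n_rounds must be >= 1")
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("boosting requires both classes present")
        w_pos = (len(y) - y.sum()) / y.sum() if self.balanced else 1.0
        params = {
            "max_depth": self.max_depth,
            "eta": self.learning_rate,
            "lambda": self.reg_lambda,
            "base_score": 0.5,
            "tree_method": "exact",
            "nthread": 1,
            "seed": self.seed,
        }
        dtrain = xgb.DMatrix(X, label=y)
        if self.loss == "cross-entropy":
            params["objective"] = "binary:logistic"
            params["scale_pos_weight"] = w_pos
            booster = xgb.train(params, dtrain, num_boost_round=self.n_rounds)
        elif self.loss == "focal":
            booster = xgb.train(params, dtrain, num_boost_round=self.n_rounds,
                                obj=_focal_objective(self.focal_gamma, w_pos))
        else:
            raise ValueError("boosting supports 'cross-entropy' and 'focal' losses")
        trees = _parse_dump(booster)
        best_k = len(trees)
        if eval_set is not None:
            best_k = self._early_stop_round(trees, eval_set, eval_metric, eval_context)
        self.booster_ = booster
        self.trees_ = trees[:best_k]
        self.best_iteration_ = best_k
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        return self

    def _early_stop_round(self, trees, eval_set, metric, context) -> int:
        Xv, yv = eval_set
        X32 = np.asarray(Xv, dtype=np.float32)
        contrib = np.stack([_eval_tree(t, X32) for t in trees])   # (K, P)
        margins = np.cumsum(contrib, axis=0)
        best_val, best_k, since = -np.inf, 1, 0
        for k in range(1, len(trees) + 1):
            val = _margin_metric(margins[k - 1], yv, metric, context)
            if val > best_val + 1e-12:
                best_val, best_k, since = val, k, 0
            else:
                since += 1
                if since >= self.patience:
                    break
        return best_k

    def decision_function(self, X):
        margin, _ = ensemble_score(self.trees_, X)
        return margin

    def predict_proba(self, X):
        _, p = ensemble_score(self.trees_, X)
        return np.stack([1.0 - p, p], axis=1)

    def predict(self, X):
        return (self.decision_function(X) >= 0.0).astype(int)


def _margin_metric(margin: np.ndarray, y: np.ndarray, metric: str, context) -> float:
    """Holdout metric from raw margins; higher is better (loss negated)."""
    p = 1.0 / (1.0 + np.exp(-margin))
    y = np.asarray(y, dtype=int)
    if metric == "loss":
        eps = 1e-12
        return float(np.mean(y * np.log(p + eps) + (1 - y) * np.log(1 - p + eps)))
    if metric in ("MCC", "F1"):
        pred = p >= 0.5
        c = ConfusionCounts(
            tp=int(np.sum(pred & (y == 1))), fp=int(np.sum(pred & (y == 0))),
            tn=int(np.sum(~pred & (y == 0))), fn=int(np.sum(~pred & (y == 1))),
        )
        return derived_metrics(c)[metric]
    if metric == "top_l":
        pairs, fams, L_by_family = context
        vals = []
        for fam in sorted(set(fams.tolist())):
            m = fams == fam
            L = L_by_family[fam]
            scores = pairs_to_scores(pairs[m], p[m], L)
            labels = ContactLabels(_pairs_to_matrix(pairs[m], y[m], L))
            vals.append(top_kl_precision(scores, labels, 1.0, L))
        return float(np.mean(vals))
    raise ValueError(f"unknown metric {metric!r}")


def _pairs_to_matrix(pairs, y, L):
    m = np.zeros((L, L), dtype=np.int8)
    m[pairs[:, 0], pairs[:, 1]] = y
    m[pairs[:, 1], pairs[:, 0]] = y
    return m


# ---------------------------------------------------------------------------
# training regimes


def _family_tables(backbone: AxialBackbone, families, min_separation: int):
    tables = []
    for fam in families:
        _, maps = backbone.forward_collect(fam.grid, mode="eval")
        tables.append(extract_pair_features(maps, min_separation, fam.labels,
                                            fam.family_id))
    return tables


def _holdout_metrics(backbone, head_w: np.ndarray, holdout, min_separation,
                     loss_kind, balanced) -> dict:
    tables = _family_tables(backbone, holdout, min_separation)
    per_top = []
    all_p, all_y = [], []
    per_counts = []
    for fam, t in zip(holdout, tables):
        z = t.X @ head_w
        p = 1.0 / (1.0 + np.exp(-z))
        all_p.append(p)
        all_y.append(t.y)
        scores = pairs_to_scores(t.pairs, p, fam.labels.L, min_separation)
        per_top.append(top_kl_precision(scores, fam.labels, 1.0))
        per_counts.append(confusion_counts(scores, fam.labels, 0.5))
    p = np.concatenate(all_p)
    y = np.concatenate(all_y)
    loss = pair_loss(nn.Tensor(p), y, loss_kind, balanced).item()
    pooled = per_counts[0]
    for c in per_counts[1:]:
        pooled = pooled + c
    d = derived_metrics(pooled)
    return {"loss": loss, "MCC": d["MCC"], "F1": d["F1"],
            "top_l": float(np.mean(per_top))}


@dataclass
class LogisticFitResult:
    head: LogisticContactHead
    checkpoints: dict            # metric -> {"coef": ..., "backbone": state or None, "value": ...}
    history: list
    backbone_frozen: bool


def _subsample_families(families, max_E, seed):
    """Deterministic row subsample per family (columns untouched, so labels
    stay aligned); used to bound the cost of fine-tuning passes."""
    from .msa import crop_and_subsample

    if max_E is None:
        return list(families)
    return [
        LabeledFamily(crop_and_subsample(f.grid, f.grid.length, max_E, seed + k),
                      f.labels, f.family_id)
        for k, f in enumerate(families)
    ]


def fit_logistic(families, backbone: AxialBackbone, plan: EarlyStopPlan,
                 loss_kind: str = "cross-entropy", backbone_frozen: bool = True,
                 min_separation: int = 4, learning_rate: float = 0.05,
                 backbone_learning_rate: float = 1e-3, max_epochs: int = 200,
                 balanced: bool = True, max_E: int | None = None,
                 seed: int = 0) -> LogisticFitResult:
    """Train the bias-free logistic head, optionally fine-tuning the backbone.

    ``families`` must contain the plan's holdout families; they are split off
    and never trained on.  A checkpoint (head weights, and backbone state
    when unfrozen) is recorded at the best value of every plan metric; the
    loop stops once no monitored metric improved for ``plan.patience``
    epochs."""
    hold_ids = set(plan.holdout)
    families = _subsample_families(families, max_E, seed)
    train = [f for f in families if f.family_id not in hold_ids]
    holdout = [f for f in families if f.family_id in hold_ids]
    if not holdout:
        raise ValueError("early-stop plan names no holdout family present in the data")
    if not train:
        raise ValueError("no training families left after holdout split")
    rng = np.random.default_rng(seed)
    n_ch = backbone.cfg.n_blocks * backbone.cfg.n_heads
    w = nn.Parameter(rng.normal(0.0, 0.01, size=n_ch))
    opt = nn.Adam([w], lr=learning_rate)
    if not backbone_frozen:
        # separate, smaller step size for backbone parameters
        opt_bb = nn.Adam(backbone.parameters(), lr=backbone_learning_rate)
    frozen_tables = None
    if backbone_frozen:
        frozen_tables = _family_tables(backbone, train, min_separation)
    best = {m: {"value": -np.inf, "coef": None, "backbone": None} for m in plan.metrics}
    history, since_improved = [], 0
    for epoch in range(max_epochs):
        if backbone_frozen:
            tab = concat_tables(frozen_tables)
            opt.zero_grad()
            p = (nn.Tensor(tab.X) @ w).sigmoid()
            loss = pair_loss(p, tab.y, loss_kind, balanced)
            loss.backward()
            opt.step()
        else:
            for fam in train:
                opt.zero_grad()
                opt_bb.zero_grad()
                _, maps_t = backbone.collect_maps_tensor(fam.grid, train=False)
                pairs = included_pairs(fam.labels.L, min_separation)
                keep = ~fam.labels.excluded_mask[pairs[:, 0], pairs[:, 1]]
                pairs = pairs[keep]
                m1 = maps_t[:, pairs[:, 0], pairs[:, 1]]
                m2 = maps_t[:, pairs[:, 1], pairs[:, 0]]
                Xp = ((m1 + m2) * 0.5).transpose(1, 0)
                yv = fam.labels.matrix[pairs[:, 0], pairs[:, 1]].astype(int)
                p = (Xp @ w).sigmoid()
                loss = pair_loss(p, yv, loss_kind, balanced)
                loss.backward()
                opt.step()
                opt_bb.step()
        vals = _holdout_metrics(backbone, w.data, holdout, min_separation,
                                loss_kind, balanced)
        history.append(vals)
        improved = False
        for m in plan.metrics:
            score = -vals["loss"] if m == "loss" else vals[m]
            if score > best[m]["value"] + 1e-12:
                best[m] = {
                    "value": score,
                    "coef": w.data.copy(),
                    "backbone": None if backbone_frozen else backbone.state_arrays(),
                }
                improved = True
        since_improved = 0 if improved else since_improved + 1
        if since_improved >= plan.patience:
            break
    # final head: checkpoint of the first plan metric
    primary = best[plan.metrics[0]]
    head = LogisticContactHead(loss=loss_kind, balanced=balanced, seed=seed)
    head.coef_ = primary["coef"].copy()
    head.classes_ = np.array([0, 1])
    head.n_features_in_ = n_ch
    if not backbone_frozen and primary["backbone"] is not None:
        backbone.load_state_arrays(primary["backbone"])
    return LogisticFitResult(head, best, history, backbone_frozen)


def fit_boosted(families, backbone: AxialBackbone, plan: EarlyStopPlan,
                loss_kind: str = "cross-entropy", rounds: int = 200,
                min_separation: int = 4, max_depth: int = 3,
                learning_rate: float = 0.1, max_E: int | None = None,
                seed: int = 0) -> BoostedContactEnsemble:
    """Fit the boosted CART ensemble on frozen-backbone attention features."""
    hold_ids = set(plan.holdout)
    families = _subsample_families(families, max_E, seed)
    train = [f for f in families if f.family_id not in hold_ids]
    holdout = [f for f in families if f.family_id in hold_ids]
    if not holdout or not train:
        raise ValueError("plan must leave both training and holdout families")
    train_tab = concat_tables(_family_tables(backbone, train, min_separation))
    hold_tab = concat_tables(_family_tables(backbone, holdout, min_separation))
    ens = BoostedContactEnsemble(n_rounds=rounds, max_depth=max_depth,
                                 learning_rate=learning_rate, loss=loss_kind,
                                 patience=plan.patience, seed=seed)
    context = (hold_tab.pairs, hold_tab.family_ids, hold_tab.L_by_family)
    ens.fit(train_tab.X, train_tab.y, eval_set=(hold_tab.X, hold_tab.y),
            eval_metric=plan.metrics[0], eval_context=context)
    return ens


def finetune_then_boost(backbone: AxialBackbone, families,
                        finetune_plan: EarlyStopPlan, boost_plan: EarlyStopPlan,
                        loss_kind: str = "cross-entropy", rounds: int = 200,
                        min_separation: int = 4, max_epochs: int = 60,
                        max_E: int | None = None, seed: int = 0) -> dict:
    """Fine-tune the backbone via the logistic proxy, then boost on its features.

    The backbone is fine-tuned with the regression head (unfrozen), the
    checkpoint for ``finetune_plan.metrics[0]`` is selected as feature
    extractor, and the CART ensemble is fit on the re-extracted features with
    its own early-stop metric.  Returns a record carrying the ensemble, the
    selected backbone state and both early-stop metrics (provenance)."""
    ft = fit_logistic(families, backbone, finetune_plan, loss_kind=loss_kind,
                      backbone_frozen=False, min_separation=min_separation,
                      max_epochs=max_epochs, max_E=max_E, seed=seed)
    chosen = ft.checkpoints[finetune_plan.metrics[0]]
    if chosen["backbone"] is None:
        raise ValueError(f"no checkpoint recorded for metric {finetune_plan.metrics[0]!r}")
    backbone.load_state_arrays(chosen["backbone"])
    ens = fit_boosted(families, backbone, boost_plan, loss_kind=loss_kind,
                      rounds=rounds, min_separation=min_separation,
                      max_E=max_E, seed=seed)
    return {
        "ensemble": ens,
        "backbone_state": backbone.state_arrays(),
        "finetune_result": ft,
        "provenance": {
            "finetune_metric": finetune_plan.metrics[0],
            "boost_metric": boost_plan.metrics[0],
        },
    }


def predict_contacts(backbone: AxialBackbone, model, grid: TokenGrid,
                     min_separation: int = 4) -> ContactScores:
    """Score all included pairs of one family with a fitted head."""
    _, maps = backbone.forward_collect(grid, mode="eval")
    table = extract_pair_features(maps, min_separation)
    p = model.predict_proba(table.X)[:, 1]
    return pairs_to_scores(table.pairs, p, grid.length, min_separation)


# ---------------------------------------------------------------------------
# model files


def save_model(model, path, backbone_hash: str = "", provenance: dict | None = None):
    """Serialise a head to JSON (weights or tree dump + provenance)."""
    if isinstance(model, LogisticContactHead):
        payload = {
            "kind": "logistic",
            "coef": model.coef_.tolist(),
            "loss": model.loss,
            "backbone_hash": backbone_hash,
            "provenance": provenance or {},
        }
    elif isinstance(model, BoostedContactEnsemble):
        payload = {
            "kind": "boosted",
            "trees": model.trees_,
            "loss": model.loss,
            "best_iteration": model.best_iteration_,
            "backbone_hash": backbone_hash,
            "provenance": provenance or {},
        }
    else:
        raise TypeError(f"cannot serialise {type(model).__name__}")
    with open(path, "w") as fh:
        json.dump(payload, fh, sort_keys=True, indent=1)


def load_model(path):
    with open(path) as fh:
        payload = json.load(fh)
    if payload["kind"] == "logistic":
        head = LogisticContactHead(loss=payload["loss"])
        head.coef_ = np.asarray(payload["coef"], dtype=float)
        head.classes_ = np.array([0, 1])
        head.n_features_in_ = len(head.coef_)
        return head, payload
    if payload["kind"] == "boosted":
        ens = BoostedContactEnsemble(loss=payload["loss"])
        ens.trees_ = payload["trees"]
        ens.best_iteration_ = payload["best_iteration"]
        ens.classes_ = np.array([0, 1])
        return ens, payload
    raise ValueError(f"unknown model kind {payload['kind']!r}")
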