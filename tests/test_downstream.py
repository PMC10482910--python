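"""Downstream contact heads: features, logistic, boosting, fine-tuning."""

import numpy as np
import pytest

from rnacontact import msa as M
from rnacontact import nn
from rnacontact import downstream as D
from rnacontact.backbone import AttentionMaps, AxialBackbone, BackboneConfig
from rnacontact.metrics import derived_metrics


def _maps(rng, C=8, L=10):
    return AttentionMaps(rng.normal(size=(C, L, L)),
                         [(b, h) for b in range(C // 4) for h in range(4)])


# ---------------------------------------------------------------------------
# features

def test_symmetric_maps_feature_equals_pixel(rng):
    raw = rng.normal(size=(3, 8, 8))
    sym = 0.5 * (raw + raw.transpose(0, 2, 1))
    maps = AttentionMaps(sym, [(0, 0), (0, 1), (0, 2)])
    t = D.extract_pair_features(maps, min_separation=2)
    for (i, j), x in zip(t.pairs, t.X):
        np.testing.assert_allclose(x, sym[:, i, j])


def test_pair_count_L10_minsep4(rng):
    t = D.extract_pair_features(_maps(rng), min_separation=4)
    # pairs i<j with j-i>=4 for L=10: enumerated = 21
    assert len(t.pairs) == sum(1 for i in range(10) for j in range(i + 4, 10))
    assert len(t.pairs) == 21
    assert t.n_features == 8


def test_features_symmetrized_mean(rng):
    maps = _maps(rng)
    t = D.extract_pair_features(maps, min_separation=4)
    i, j = t.pairs[0]
    np.testing.assert_allclose(
        t.X[0], 0.5 * (maps.maps[:, i, j] + maps.maps[:, j, i]))


# ---------------------------------------------------------------------------
# logistic head

def test_logistic_zero_vector_gives_half():
    head = D.LogisticContactHead()
    head.coef_ = np.array([0.3, -0.7])
    assert head.predict_proba(np.zeros((1, 2)))[0, 1] == pytest.approx(0.5)


def test_logistic_log_odds_identity():
    head = D.LogisticContactHead()
    head.coef_ = np.array([np.log(3.0)])
    assert head.predict_proba(np.ones((1, 1)))[0, 1] == pytest.approx(0.75)


def test_logistic_negation_symmetry(rng):
    X = rng.normal(size=(20, 4))
    w = rng.normal(size=4)
    h1, h2 = D.LogisticContactHead(), D.LogisticContactHead()
    h1.coef_, h2.coef_ = w, -w
    p1 = h1.predict_proba(X)[:, 1]
    p2 = h2.predict_proba(X)[:, 1]
    np.testing.assert_allclose(p1 + p2, 1.0, atol=1e-12)


def test_logistic_separable_toy_reaches_mcc_one(rng):
    X = np.vstack([rng.normal(2.0, 0.3, size=(40, 2)),
                   rng.normal(-2.0, 0.3, size=(40, 2))])
    y = np.array([1] * 40 + [0] * 40)
    head = D.LogisticContactHead(max_epochs=400, learning_rate=0.1).fit(X, y)
    pred = head.predict(X)
    tp = int(np.sum((pred == 1) & (y == 1)))
    tn = int(np.sum((pred == 0) & (y == 0)))
    from rnacontact.metrics import ConfusionCounts
    c = ConfusionCounts(tp=tp, tn=tn, fp=40 - tn, fn=40 - tp)
    assert derived_metrics(c)["MCC"] == 1.0


def test_logistic_fit_deterministic(rng):
    X = rng.normal(size=(50, 3))
    y = (X[:, 0] > 0).astype(int)
    a = D.LogisticContactHead(seed=5, max_epochs=50).fit(X, y).coef_
    b = D.LogisticContactHead(seed=5, max_epochs=50).fit(X, y).coef_
    np.testing.assert_array_equal(a, b)


@pytest.mark.parametrize("kind", ["cross-entropy", "focal", "dice"])
def test_pair_losses_decrease_with_better_predictions(kind):
    y = np.array([1, 0, 1, 0, 0, 0])
    good = nn.Tensor(np.where(y == 1, 0.9, 0.1).astype(float))
    bad = nn.Tensor(np.full(6, 0.5))
    assert D.pair_loss(good, y, kind).item() < D.pair_loss(bad, y, kind).item()


# ---------------------------------------------------------------------------
# boosted ensemble algebra

def test_empty_ensemble_scores_log_odds_zero():
    margin, prob = D.ensemble_score([], np.ones((1, 3)))
    assert margin[0] == 0.0 and prob[0] == pytest.approx(0.5)


def test_hand_built_stumps_sum():
    stump1 = {"nodeid": 0, "split": "f0", "split_condition": 0.5, "yes": 1,
              "no": 2, "children": [{"nodeid": 1, "leaf": 0.5},
                                    {"nodeid": 2, "leaf": -1.0}]}
    stump2 = {"nodeid": 0, "leaf": -0.2}
    margin, prob = D.ensemble_score([stump1, stump2], np.array([[0.0]]))
    assert margin[0] == pytest.approx(0.3)
    assert prob[0] == pytest.approx(1 / (1 + np.exp(-0.3)))


def test_zero_leaf_tree_is_noop(rng):
    X = rng.normal(size=(5, 2))
    stump = {"nodeid": 0, "split": "f1", "split_condition": 0.0, "yes": 1,
             "no": 2, "children": [{"nodeid": 1, "leaf": 0.0},
                                   {"nodeid": 2, "leaf": 0.0}]}
    base = {"nodeid": 0, "leaf": 0.7}
    m1, _ = D.ensemble_score([base], X)
    m2, _ = D.ensemble_score([base, stump], X)
    np.testing.assert_array_equal(m1, m2)


def test_own_evaluation_matches_xgboost_margin(rng):
    X = rng.normal(size=(200, 5))
    y = ((X[:, 0] + X[:, 1] * X[:, 2]) > 0).astype(int)
    ens = D.BoostedContactEnsemble(n_rounds=30, seed=1).fit(X, y)
    own = ens.decision_function(X)
    import xgboost as xgb
    ref = ens.booster_.predict(xgb.DMatrix(X), output_margin=True)
    np.testing.assert_allclose(own, ref, atol=1e-5)


def test_xor_separable_by_trees_not_by_biasfree_linear(rng):
    X = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]] * 10)
    X = X + rng.normal(0, 0.05, size=X.shape)
    y = (np.sign(X[:, 0]) != np.sign(X[:, 1])).astype(int)
    ens = D.BoostedContactEnsemble(n_rounds=50, max_depth=2,
                                   learning_rate=0.5, seed=0).fit(X, y)
    assert (ens.predict(X) == y).mean() == 1.0
    # brute-force bound for any bias-free linear rule sign(w.x)
    best = 0.0
    for theta in np.linspace(0, 2 * np.pi, 721):
        w = np.array([np.cos(theta), np.sin(theta)])
        acc = ((X @ w >= 0).astype(int) == y).mean()
        best = max(best, acc)
    assert best <= 0.75


def test_training_logloss_monotone_in_rounds(rng):
    X = rng.normal(size=(150, 4))
    y = (X[:, 0] > 0.2).astype(int)

    def logloss(k):
        ens = D.BoostedContactEnsemble(n_rounds=k, balanced=False, seed=2).fit(X, y)
        p = ens.predict_proba(X)[:, 1]
        return -np.mean(y * np.log(p + 1e-12) + (1 - y) * np.log(1 - p + 1e-12))

    assert logloss(10) <= logloss(1) + 1e-12


def test_boosting_deterministic(rng):
    X = rng.normal(size=(100, 3))
    y = (X.sum(1) > 0).astype(int)
    t1 = D.BoostedContactEnsemble(n_rounds=15, seed=3).fit(X, y).trees_
    t2 = D.BoostedContactEnsemble(n_rounds=15, seed=3).fit(X, y).trees_
    assert t1 == t2


def test_single_class_labels_rejected(rng):
    X = rng.normal(size=(10, 2))
    with pytest.raises(ValueError, match="both classes"):
        D.BoostedContactEnsemble().fit(X, np.ones(10, dtype=int))


def test_focal_objective_trains(rng):
    X = rng.normal(size=(120, 3))
    y = (X[:, 1] > 0.5).astype(int)
    ens = D.BoostedContactEnsemble(n_rounds=40, loss="focal", seed=4).fit(X, y)
    assert (ens.predict(X) == y).mean() > 0.9
    with pytest.raises(ValueError, match="supports"):
        D.BoostedContactEnsemble(loss="dice").fit(X, y)


# ---------------------------------------------------------------------------
# training regimes on a tiny synthetic setup

def _tiny_setup(seed=0, n_fams=4, L=20, E=40):
    from rnacontact import synthetic
    fams = []
    for s in range(n_fams):
        fam = synthetic.make_family(50 + seed + s, L=L, E=E, n_pairs=3,
                                    family_id=f"T{s}")
        fams.append(D.LabeledFamily(M.tokenize(fam.msa), fam.labels, f"T{s}"))
    cfg = BackboneConfig(n_blocks=2, n_heads=2, embed_dim=16, dropout_p=0.0,
                         mlp_hidden=32, max_len=64)
    return fams, AxialBackbone(cfg, seed=seed)


def test_frozen_fit_leaves_backbone_bitwise_unchanged():
    fams, bb = _tiny_setup()
    before = {k: v.data.copy() for k, v in bb.params.items()}
    plan = D.EarlyStopPlan(metrics=("loss",), patience=3, holdout=("T3",))
    D.fit_logistic(fams, bb, plan, max_epochs=5, seed=1)
    for k in before:
        np.testing.assert_array_equal(bb.params[k].data, before[k])


def test_fit_logistic_deterministic():
    fams, bb = _tiny_setup()
    plan = D.EarlyStopPlan(metrics=("loss",), patience=3, holdout=("T3",))
    w1 = D.fit_logistic(fams, bb, plan, max_epochs=5, seed=2).head.coef_
    w2 = D.fit_logistic(fams, bb, plan, max_epochs=5, seed=2).head.coef_
    np.testing.assert_array_equal(w1, w2)


def test_fit_logistic_requires_holdout_present():
    fams, bb = _tiny_setup()
    plan = D.EarlyStopPlan(metrics=("loss",), patience=3, holdout=("NOPE",))
    with pytest.raises(ValueError, match="holdout"):
        D.fit_logistic(fams, bb, plan, max_epochs=2)


def test_finetuning_changes_features_and_records_provenance():
    fams, bb = _tiny_setup()
    ft_plan = D.EarlyStopPlan(metrics=("top_l",), patience=3, holdout=("T3",))
    b_plan = D.EarlyStopPlan(metrics=("MCC",), patience=3, holdout=("T3",))
    frozen_maps = bb.forward_collect(fams[0].grid, "eval")[1].maps.copy()
    rec = D.finetune_then_boost(bb, fams, ft_plan, b_plan, max_epochs=4,
                                rounds=10, seed=3)
    assert rec["provenance"] == {"finetune_metric": "top_l",
                                 "boost_metric": "MCC"}
    tuned_maps = bb.forward_collect(fams[0].grid, "eval")[1].maps
    assert not np.allclose(frozen_maps, tuned_maps)


def test_predicted_score_matrix_is_symmetric_and_probabilistic():
    fams, bb = _tiny_setup()
    plan = D.EarlyStopPlan(metrics=("loss",), patience=2, holdout=("T3",))
    res = D.fit_logistic(fams, bb, plan, max_epochs=3, seed=4)
    scores = D.predict_contacts(bb, res.head, fams[0].grid)
    np.testing.assert_array_equal(scores.matrix, scores.matrix.T)
    iu, ju = np.triu_indices(scores.L, k=1)
    inc = ~scores.excluded_mask[iu, ju]
    assert ((scores.matrix[iu, ju][inc] > 0) & (scores.matrix[iu, ju][inc] < 1)).all()


def test_model_file_round_trip(tmp_path, rng):
    X = rng.normal(size=(60, 4))
    y = (X[:, 0] > 0).astype(int)
    head = D.LogisticContactHead(max_epochs=30).fit(X, y)
    D.save_model(head, tmp_path / "h.json", backbone_hash="abc")
    loaded, payload = D.load_model(tmp_path / "h.json")
    np.testing.assert_array_equal(loaded.coef_, head.coef_)
    assert payload["backbone_hash"] == "abc"

    ens = D.BoostedContactEnsemble(n_rounds=10, seed=0).fit(X, y)
    D.save_model(ens, tmp_path / "e.json", backbone_hash="abc")
    loaded_e, _ = D.load_model(tmp_path / "e.json")
    np.testing.assert_allclose(loaded_e.decision_function(X),
                               ens.decision_function(X))
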