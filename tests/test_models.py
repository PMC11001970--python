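"""Model zoo: rebalancing, early stopping, rule/BoW behaviour, the numpy
nets (gradients checked against numerical differentiation), and the
shared prediction contract."""

import numpy as np
import pytest

from psychonc.cohort import TokenSeq
from psychonc.metrics import confusion_metrics
from psychonc.models import (EarlyStopper, ModelSpec, make_model, rebalance)
from psychonc.models.nets import (BiLSTMNet, CNNNet, MeanPoolNet,
                                  TransformerNet)
from psychonc.presets import bigram_signal_config, null_config, toy_spec
from psychonc import (apply_exclusions, assign_labels, generate_registry,
                      split_ids)


def bow_seqs(token_lists):
    return [TokenSeq("bow", tuple(toks)) for toks in token_lists]


# ---------------------------------------------------------------------------
# rebalancing


def test_undersample_one_to_one(rng):
    labels = np.array([1] * 10 + [0] * 1000)
    idx, w = rebalance(labels, "undersample", rng)
    assert (labels[idx] == 1).sum() == 10
    assert (labels[idx] == 0).sum() == 10
    assert len(set(idx)) == len(idx), "no record duplicated"
    assert set(np.flatnonzero(labels == 1)) <= set(idx), "every positive kept"


def test_loss_weighting_inverse_frequency(rng):
    n = 10_000
    labels = np.zeros(n, dtype=int)
    labels[:140] = 1  # prevalence 1.4%
    idx, w = rebalance(labels, "loss_weighting", rng)
    assert len(idx) == n
    ratio = w[labels == 1][0] / w[labels == 0][0]
    assert ratio == pytest.approx((1 - 0.014) / 0.014)  # ~70.4 : 1


def test_balanced_input_identity(rng):
    labels = np.array([0, 1] * 20)
    idx, w = rebalance(labels, "undersample", rng)
    assert len(idx) == 40
    idx, w = rebalance(labels, "loss_weighting", rng)
    assert np.allclose(w, 1.0)


def test_single_class_rejected(rng):
    with pytest.raises(ValueError, match="both classes"):
        rebalance(np.ones(5, dtype=int), "undersample", rng)


# ---------------------------------------------------------------------------
# early stopping


def test_patience_stops_five_epochs_after_peak():
    """Dev BAC peaks at epoch 3 then declines: training runs to epoch 8
    and the epoch-3 checkpoint is kept."""
    stopper = EarlyStopper(patience=5)
    trace = [0.6, 0.65, 0.7, 0.68, 0.66, 0.64, 0.62, 0.60, 0.58]
    cont = [stopper.update(v) for v in trace]
    assert cont[:7] == [True] * 7
    assert cont[7] is False  # epoch 8 is the stopping epoch
    assert stopper.best_epoch == 3
    assert stopper.best_value == 0.7


def test_min_epochs_defers_stopping():
    stopper = EarlyStopper(patience=2, min_epochs=6)
    assert all(stopper.update(0.5) for _ in range(5))
    assert stopper.update(0.5) is False  # epoch 6 reached, patience long gone


def test_best_checkpoint_never_later_than_best_epoch(small_dataset):
    """Restored parameters equal those of a run stopped exactly at the
    best epoch (same seed, same data order)."""
    ds = small_dataset
    tr, dv = ds.tokens("neural", "train"), ds.tokens("neural", "dev")
    ytr, ydv = ds.labels("train"), ds.labels("dev")
    spec = toy_spec("cnn", seed=5, max_epochs=12, min_epochs=1, patience=3)
    m1 = make_model(spec).fit(tr, ytr, dv, ydv)
    assert 1 <= m1.best_epoch <= m1.epochs_trained
    spec2 = toy_spec("cnn", seed=5, max_epochs=m1.best_epoch, min_epochs=1,
                     patience=3)
    m2 = make_model(spec2).fit(tr, ytr, dv, ydv)
    te = ds.tokens("neural", "test")
    assert np.allclose(m1.predict_proba(te), m2.predict_proba(te))


# ---------------------------------------------------------------------------
# rule-based comparator


def test_rule_trigger_tokens():
    psych = make_model(ModelSpec(family="rule", target="psychiatrist"))
    coun = make_model(ModelSpec(family="rule", target="counsellor"))
    doc_p = bow_seqs([["patient", "saw", "psychiatrist"]])
    doc_c = bow_seqs([["counsel"]])  # "counselling" stems to this
    empty = bow_seqs([[]])
    assert psych.predict_proba(doc_p)[0] == 1.0
    assert psych.predict_proba(doc_c)[0] == 0.0
    assert coun.predict_proba(doc_c)[0] == 1.0
    assert coun.predict_proba(empty)[0] == 0.0
    assert psych.predict_proba(empty)[0] == 0.0


# ---------------------------------------------------------------------------
# bag-of-words


def test_bow_redundant_features_split_ridge_weight(rng):
    """Two perfectly redundant tokens share the weight of the single
    token fitted at doubled C (the analytic ridge equivalence)."""
    n = 400
    y = rng.integers(0, 2, size=n)
    noise = rng.integers(0, 2, size=n)
    dup = [["sig", "dup"] * y[i] + ["noise"] * noise[i] + ["base"]
           for i in range(n)]
    single = [["sig"] * y[i] + ["noise"] * noise[i] + ["base"]
              for i in range(n)]
    spec = ModelSpec(family="bow", target="psychiatrist", min_df=1,
                     C_grid=(1.0,))
    m_dup = make_model(spec).fit(bow_seqs(dup), y, None, None)
    spec2 = ModelSpec(family="bow", target="psychiatrist", min_df=1,
                      C_grid=(2.0,))
    m_single = make_model(spec2).fit(bow_seqs(single), y, None, None)
    c_dup = m_dup.coefficients()
    assert c_dup["sig"] == pytest.approx(c_dup["dup"], rel=1e-4)
    assert c_dup["sig"] == pytest.approx(
        m_single.coefficients()["sig"] / 2, rel=1e-2)


def test_bow_empty_vocabulary_rejected():
    spec = ModelSpec(family="bow", target="psychiatrist", min_df=5)
    with pytest.raises(ValueError, match="empty vocabulary"):
        make_model(spec).fit(bow_seqs([["one", "two"]]), [0, 1][:1],
                             None, None)


def test_null_corpus_auc_within_chance_band():
    """Zero-effect config: trained BoW stays inside the null AUC band."""
    reg = generate_registry(null_config(3000, seed=8))
    ds = assign_labels(apply_exclusions(reg), "psychiatrist")
    ds.partition = split_ids([it.doc_id for it in ds.items], rng=1)
    spec = toy_spec("bow", seed=0)
    m = make_model(spec).fit(ds.tokens("bow", "train"), ds.labels("train"),
                             ds.tokens("bow", "dev"), ds.labels("dev"))
    rep = confusion_metrics(ds.labels("test"),
                            m.predict_proba(ds.tokens("bow", "test")))
    y = ds.labels("test")
    n1, n0 = int(y.sum()), int((1 - y).sum())
    se_auc = np.sqrt((n1 + n0 + 1) / (12 * n1 * n0))
    assert abs(rep.auc - 0.5) < 3.5 * se_auc
    assert abs(rep.bac - 0.5) < 3.5 * se_auc


# ---------------------------------------------------------------------------
# numpy nets: gradient correctness


@pytest.mark.parametrize("net", [
    MeanPoolNet(5),
    CNNNet(5, widths=(2, 3), n_filters=4, dropout=0.0),
    BiLSTMNet(5, hidden_dim=4),
    BiLSTMNet(5, hidden_dim=4, pooling="mean"),
    TransformerNet(5, n_positions=16, ff_dim=4),
], ids=["meanpool", "cnn", "lstm-max", "lstm-mean", "transformer"])
def test_backprop_matches_numerical_gradient(net, rng):
    params = net.init_params(rng)
    B, L, D = 3, 7, 5
    X = rng.normal(size=(B, L, D))
    mask = np.ones((B, L))
    mask[1, 5:] = 0
    mask[2, 3:] = 0

    def f(X_):
        return net.forward(params, X_, mask)[0].sum()

    _, cache = net.forward(params, X, mask)
    grads, dX = net.backward(params, cache, np.ones(B))
    eps = 1e-6
    for _ in range(25):
        i, j, k = rng.integers(B), rng.integers(L), rng.integers(D)
        Xp, Xm = X.copy(), X.copy()
        Xp[i, j, k] += eps
        Xm[i, j, k] -= eps
        num = (f(Xp) - f(Xm)) / (2 * eps)
        assert num == pytest.approx(dX[i, j, k], abs=5e-6)
    for key, g in grads.items():
        arr = params[key]
        idx = np.unravel_index(rng.integers(arr.size), arr.shape)
        orig = arr[idx]
        arr[idx] = orig + eps
        fp = f(X)
        arr[idx] = orig - eps
        fm = f(X)
        arr[idx] = orig
        assert (fp - fm) / (2 * eps) == pytest.approx(g[idx], abs=5e-6)


# ---------------------------------------------------------------------------
# sequence-model contracts


def test_transformer_token_limit_validation():
    with pytest.raises(ValueError, match="positional capacity"):
        ModelSpec(family="transformer", target="psychiatrist",
                  max_tokens=4096, n_positions=512)
    with pytest.raises(ValueError, match="one of"):
        ModelSpec(family="transformer", target="psychiatrist",
                  max_tokens=700)
    # valid combination passes
    ModelSpec(family="transformer", target="psychiatrist",
              max_tokens=2048, n_positions=2048)


def test_fixed_seed_is_deterministic(small_dataset):
    ds = small_dataset
    tr, dv, te = (ds.tokens("neural", p) for p in ("train", "dev", "test"))
    spec = toy_spec("cnn", seed=9, max_epochs=4, min_epochs=1)
    p1 = make_model(spec).fit(tr, ds.labels("train"), dv,
                              ds.labels("dev")).predict_proba(te)
    p2 = make_model(spec).fit(tr, ds.labels("train"), dv,
                              ds.labels("dev")).predict_proba(te)
    assert np.array_equal(p1, p2)


def test_all_families_share_score_contract(small_dataset):
    ds = small_dataset
    for family in ("rule", "bow", "cnn", "lstm"):
        spec = toy_spec(family, seed=2, max_epochs=3, min_epochs=1,
                        hidden_dim=8)
        d = spec.dialect
        m = make_model(spec).fit(ds.tokens(d, "train"), ds.labels("train"),
                                 ds.tokens(d, "dev"), ds.labels("dev"))
        scores = m.predict_proba(ds.tokens(d, "test")[:20])
        assert scores.shape == (20,)
        assert np.all((scores >= 0) & (scores <= 1))


def test_order_sensitive_signal_cnn_beats_bow():
    """The phrase "also noticed" raises the outcome odds while its
    reversal lowers them; unigram counts carry nothing, so the CNN's
    adjacent-word convolutions must beat the BoW model."""
    reg = generate_registry(bigram_signal_config(3000, seed=6))
    ds = assign_labels(apply_exclusions(reg), "psychiatrist")
    ds.partition = split_ids([it.doc_id for it in ds.items], rng=2)
    reports = {}
    for family in ("bow", "cnn"):
        spec = toy_spec(family, seed=4, max_tokens=128)
        d = spec.dialect
        m = make_model(spec).fit(ds.tokens(d, "train"), ds.labels("train"),
                                 ds.tokens(d, "dev"), ds.labels("dev"))
        reports[family] = confusion_metrics(
            ds.labels("test"), m.predict_proba(ds.tokens(d, "test")))
    assert reports["bow"].bac < 0.60, "unigrams are uninformative"
    assert reports["cnn"].bac > reports["bow"].bac + 0.08


# ---------------------------------------------------------------------------
# artifact serialization


def test_model_artifacts_round_trip(tmp_path, small_dataset):
    """Saved artifact (.npz + JSON sidecar) reloads to identical scores."""
    from psychonc.models import load_model, save_model

    ds = small_dataset
    te_bow, te_neural = ds.tokens("bow", "test")[:15], \
        ds.tokens("neural", "test")[:15]
    bow = make_model(toy_spec("bow", seed=1)).fit(
        ds.tokens("bow", "train"), ds.labels("train"),
        ds.tokens("bow", "dev"), ds.labels("dev"))
    cnn = make_model(toy_spec("cnn", seed=1, max_epochs=3, min_epochs=1)).fit(
        ds.tokens("neural", "train"), ds.labels("train"),
        ds.tokens("neural", "dev"), ds.labels("dev"))
    for model, seqs, name in ((bow, te_bow, "bow"), (cnn, te_neural, "cnn")):
        save_model(model, tmp_path / name)
        back = load_model(tmp_path / name)
        assert np.allclose(back.predict_proba(seqs),
                           model.predict_proba(seqs))
        assert back.epochs_trained == model.epochs_trained
        sidecar = (tmp_path / f"{name}.json").read_text()
        assert "vocabulary_hash" in sidecar
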