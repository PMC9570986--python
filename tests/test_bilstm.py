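"""BiLSTM cell equations, gradients, training and warm starts."""

import math

import numpy as np
import pytest
from sklearn.base import clone

import emgtremor as et
from emgtremor.bilstm import (
    BiLSTMClassifier, CellState, LSTMCellParams, init_model, loss_and_grads,
    lstm_step, bilstm_forward, predict_proba, save_model, load_model, train,
    warm_start,
)

HYPER = {"n_neurons": 4, "learning_rate": 1e-2, "n_epochs": 5,
         "batch_size": 16, "optimizer": "Adam", "activation": "tanh"}


def _sigmoid(x):
    return 1.0 / (1.0 + math.exp(-x))


# ---------------------------------------------------------------------------
# initialization


def test_init_deterministic_and_seed_sensitive():
    a = init_model(HYPER, classes=["a", "b"], seed=3)
    b = init_model(HYPER, classes=["a", "b"], seed=3)
    for k, v in a.parameters().items():
        np.testing.assert_array_equal(v, b.parameters()[k])
    for seed in range(50):
        c = init_model(HYPER, classes=["a", "b"], seed=seed)
        d = init_model(HYPER, classes=["a", "b"], seed=seed + 1)
        assert any(
            not np.array_equal(v, d.parameters()[k])
            for k, v in c.parameters().items()
        )


def test_init_head_dimensions():
    m = init_model({"n_neurons": 20}, classes=list("abcde"))
    assert m.head_W.shape == (5, 40)
    with pytest.raises(ValueError, match="non-empty"):
        init_model(HYPER, classes=[])


# ---------------------------------------------------------------------------
# cell equations


def test_lstm_step_zero_weights_zero_state():
    cell = LSTMCellParams("paper_literal", 2, 3, "tanh", W=np.zeros((8, 3)))
    out = lstm_step(cell, np.zeros(3), CellState.zeros(2))
    np.testing.assert_array_equal(out.h, 0.0)
    np.testing.assert_array_equal(out.c, 0.0)


def test_lstm_step_scalar_literal_oracle():
    """Hand evaluation of the literal cell: all weights 1, x=1, zero state.

    Gates are sigma(1); c = sigma(1)*tanh(1); h = tanh(c)*sigma(1).
    """
    gate = _sigmoid(1.0)
    c_expect = gate * math.tanh(1.0)
    h_expect = math.tanh(c_expect) * gate
    cell = LSTMCellParams("paper_literal", 1, 1, "tanh", W=np.ones((4, 1)))
    out = lstm_step(cell, np.array([1.0]), CellState.zeros(1))
    assert out.c[0] == pytest.approx(c_expect, abs=1e-6)
    assert out.h[0] == pytest.approx(h_expect, abs=1e-6)
    assert out.c[0] == pytest.approx(0.5568, abs=1e-4)
    assert out.h[0] == pytest.approx(0.3697, abs=1e-4)


def test_lstm_step_memory_carry_limit():
    """Saturated forget-open/input-closed gates carry the cell state."""
    h = 1
    W = np.zeros((4, 1))
    U = np.zeros((4, 1))
    b = np.array([-30.0, 30.0, 0.0, 0.0])  # input gate shut, forget gate open
    cell = LSTMCellParams("standard", h, 1, "tanh", W=W, U=U, b=b)
    state = CellState(h=np.array([0.3]), c=np.array([0.8]))
    out = lstm_step(cell, np.array([1.0]), state)
    assert out.c[0] == pytest.approx(0.8, abs=1e-9)


def test_lstm_step_shape_errors():
    cell = LSTMCellParams("paper_literal", 2, 3, "tanh", W=np.zeros((8, 3)))
    with pytest.raises(ValueError, match="shape"):
        lstm_step(cell, np.zeros(4), CellState.zeros(2))
    with pytest.raises(ValueError, match="hidden"):
        lstm_step(cell, np.zeros(3), CellState.zeros(5))


# ---------------------------------------------------------------------------
# bidirectional forward


def test_forward_probabilities_simplex():
    model = init_model(HYPER, classes=list("abc"), n_channels=8, seed=0)
    rng = np.random.default_rng(0)
    probs = predict_proba(model, rng.standard_normal((7, 12, 8)))
    assert probs.shape == (7, 3)
    assert (probs >= 0).all()
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)


def test_forward_two_step_scalar_unrolled_oracle():
    """A 2-step scalar toy model matches an independent hand unroll."""
    w = 0.7
    cell = LSTMCellParams("paper_literal", 1, 1, "tanh", W=np.full((4, 1), w))
    model = init_model({"n_neurons": 1}, classes=["a", "b"], n_channels=1,
                       seed=0, mode="paper_literal")
    model.forward_cell = cell
    model.backward_cell = LSTMCellParams(
        "paper_literal", 1, 1, "tanh", W=np.full((4, 1), w)
    )
    model.head_W = np.array([[1.0, -1.0], [-1.0, 1.0]])
    model.head_b = np.zeros(2)
    x = [0.4, -0.9]

    def unroll(seq):
        h = c = 0.0
        for xt in seq:
            i = _sigmoid(w * xt + h)
            f = _sigmoid(w * xt + h)
            o = _sigmoid(w * xt + h)
            c = f * c + i * math.tanh(w * xt)
            h = math.tanh(c) * o
        return h

    hf, hb = unroll(x), unroll(x[::-1])
    logits = np.array([hf - hb, hb - hf])
    expect = np.exp(logits) / np.exp(logits).sum()
    got = bilstm_forward(model, np.array(x)[:, None])
    np.testing.assert_allclose(got, expect, atol=1e-12)


def test_forward_direction_swap_symmetry():
    """Swapping cells, reversing time and swapping head blocks is a no-op."""
    model = init_model(HYPER, classes=list("abc"), n_channels=8, seed=5)
    rng = np.random.default_rng(1)
    window = rng.standard_normal((15, 8))
    p1 = bilstm_forward(model, window)
    h = model.hidden
    swapped = model.copy()
    swapped.forward_cell, swapped.backward_cell = (
        model.backward_cell, model.forward_cell,
    )
    swapped.head_W = np.concatenate(
        [model.head_W[:, h:], model.head_W[:, :h]], axis=1
    )
    p2 = bilstm_forward(swapped, window[::-1])
    np.testing.assert_allclose(p1, p2, atol=1e-12)


def test_forward_channel_mismatch_error():
    model = init_model(HYPER, classes=["a", "b"], n_channels=8)
    with pytest.raises(ValueError, match="channels"):
        bilstm_forward(model, np.zeros((10, 5)))


# ---------------------------------------------------------------------------
# gradients


@pytest.mark.parametrize("mode", ["paper_literal", "standard"])
@pytest.mark.parametrize("activation", ["tanh", "ReLU"])
def test_gradients_match_finite_differences(mode, activation):
    rng = np.random.default_rng(0)
    model = init_model(
        {"n_neurons": 2, "activation": activation},
        classes=["a", "b"], n_channels=2, seed=1, mode=mode,
    )
    X = rng.standard_normal((3, 4, 2))
    y = np.array([0, 1, 0])
    _, grads, _ = loss_and_grads(model, X, y)
    params = model.parameters()
    eps = 1e-5
    for name, tensor in params.items():
        it = np.nditer(tensor, flags=["multi_index"])
        for _ in it:
            ix = it.multi_index
            orig = tensor[ix]
            tensor[ix] = orig + eps
            lp, _, _ = loss_and_grads(model, X, y)
            tensor[ix] = orig - eps
            lm, _, _ = loss_and_grads(model, X, y)
            tensor[ix] = orig
            numeric = (lp - lm) / (2 * eps)
            scale = max(abs(numeric), abs(grads[name][ix]), 1e-6)
            assert abs(numeric - grads[name][ix]) / scale < 1e-4, (name, ix)


# ---------------------------------------------------------------------------
# training


def test_train_descends_and_learns(toy_two_class):
    X, y = toy_two_class
    model = init_model(
        {**HYPER, "n_epochs": 50}, classes=["a", "b"], n_channels=2, seed=0
    )
    fitted, hist = train(model, (X, y), seed=0)
    assert len(hist.loss) == 50
    assert hist.loss[-1] < hist.loss[0]
    assert hist.accuracy[-1] >= 0.95


def test_train_deterministic(toy_two_class):
    X, y = toy_two_class
    model = init_model(HYPER, classes=["a", "b"], n_channels=2, seed=0)
    m1, h1 = train(model, (X, y), seed=4)
    m2, h2 = train(model, (X, y), seed=4)
    assert h1.loss == h2.loss
    for k, v in m1.parameters().items():
        np.testing.assert_array_equal(v, m2.parameters()[k])


def test_train_input_validation(toy_two_class):
    X, y = toy_two_class
    model = init_model(HYPER, classes=["a"], n_channels=2, seed=0)
    with pytest.raises(ValueError, match="classes"):
        train(model, (X, y), seed=0)
    big = init_model({**HYPER, "batch_size": 10_000}, classes=["a", "b"],
                     n_channels=2, seed=0)
    with pytest.raises(ValueError, match="batch_size"):
        train(big, (X, y), seed=0)


# ---------------------------------------------------------------------------
# warm start


def test_warm_start_strict_copies_everything():
    src = init_model(HYPER, classes=["a", "b"], seed=1)
    tgt = init_model(HYPER, classes=["a", "b"], seed=2)
    out, frac = warm_start(tgt, src, policy="strict")
    assert frac == 1.0
    for k, v in out.parameters().items():
        np.testing.assert_array_equal(v, src.parameters()[k])


def test_warm_start_strict_mismatch_raises():
    src = init_model({**HYPER, "n_neurons": 8}, classes=["a", "b"], seed=1)
    tgt = init_model(HYPER, classes=["a", "b"], seed=2)
    with pytest.raises(ValueError, match="strict"):
        warm_start(tgt, src, policy="strict")


def test_warm_start_compatible_fraction_matches_shape_oracle():
    src = init_model({**HYPER, "n_neurons": 8}, classes=["a", "b"], seed=1)
    tgt = init_model({**HYPER, "n_neurons": 4}, classes=["a", "b"], seed=2)
    out, frac = warm_start(tgt, src, policy="compatible_only")
    sp, tp = src.parameters(), tgt.parameters()
    names = set(sp) | set(tp)
    expect = sum(
        1 for n in names
        if n in sp and n in tp and sp[n].shape == tp[n].shape
    ) / len(names)
    assert frac == expect
    # only the matching tensors were overwritten
    for n in tp:
        if n in sp and sp[n].shape == tp[n].shape:
            np.testing.assert_array_equal(out.parameters()[n], sp[n])


def test_warm_start_helps_or_matches_at_epoch_one(toy_two_class):
    """Warm-starting from a model trained on the same task is no worse
    than a cold start after the first epoch (median over 5 seeds)."""
    X, y = toy_two_class
    hyper = {**HYPER, "n_epochs": 1}
    src = init_model({**HYPER, "n_epochs": 20}, classes=["a", "b"],
                     n_channels=2, seed=0)
    trained_src, _ = train(src, (X, y), seed=0)
    deltas = []
    for seed in range(5):
        cold = init_model(hyper, classes=["a", "b"], n_channels=2, seed=seed)
        warm, _ = warm_start(cold, trained_src, policy="strict")
        _, hist_cold = train(cold, (X, y), seed=seed)
        _, hist_warm = train(warm, (X, y), seed=seed)
        deltas.append(hist_warm.accuracy[0] - hist_cold.accuracy[0])
    assert np.median(deltas) >= 0


# ---------------------------------------------------------------------------
# estimator surface and checkpoints


def test_estimator_sklearn_contract(toy_two_class):
    X, y = toy_two_class
    clf = BiLSTMClassifier(n_neurons=4, n_epochs=10, batch_size=16,
                           learning_rate=1e-2, random_state=0)
    cloned = clone(clf)
    assert cloned.get_params() == clf.get_params()
    clf.fit(X, y)
    assert list(clf.classes_) == ["a", "b"]
    preds = clf.predict(X)
    assert preds.shape == y.shape
    assert clf.score(X, y) >= 0.9
    probs = clf.predict_proba(X)
    np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-9)


def test_estimator_end_to_end_deterministic(toy_two_class):
    X, y = toy_two_class
    kw = dict(n_neurons=4, n_epochs=5, batch_size=16, random_state=7)
    p1 = BiLSTMClassifier(**kw).fit(X, y).predict_proba(X)
    p2 = BiLSTMClassifier(**kw).fit(X, y).predict_proba(X)
    np.testing.assert_array_equal(p1, p2)


def test_checkpoint_round_trip(tmp_path, toy_two_class):
    X, y = toy_two_class
    clf = BiLSTMClassifier(n_neurons=4, n_epochs=3, batch_size=16,
                           random_state=0).fit(X, y)
    save_model(clf.model_, tmp_path / "ckpt")
    loaded = load_model(tmp_path / "ckpt")
    for k, v in clf.model_.parameters().items():
        np.testing.assert_array_equal(v, loaded.parameters()[k])
    np.testing.assert_array_equal(
        predict_proba(loaded, X), clf.predict_proba(X)
    )
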