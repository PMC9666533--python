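"""Base forecasters: gate equations, gradients, training protocol, windows."""

import numpy as np
import pytest

from esrstack.basemodels import (
    ArchitectureSpec,
    GRUNet,
    GRUState,
    LSTMNet,
    LSTMState,
    MLPNet,
    TrainConfig,
    TrainingError,
    WindowSet,
    build_net,
    gru_step,
    lstm_step,
    make_windows,
    predict,
    train_model,
    weights_to_dict,
)
from esrstack.evaluate import mape, split_cohort
from esrstack.synth import generate_dataset


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def manual_mlp(net: MLPNet, X: np.ndarray) -> np.ndarray:
    """Independent forward recomputation: y = W3' phi(W2' phi(W1' x))."""
    act = {"relu": lambda z: np.maximum(z, 0), "tanh": np.tanh, "identity": lambda z: z}
    phi = act[net.spec.activation]
    a = X
    for W, b in zip(net.weights[:-1], net.biases[:-1]):
        a = phi(a @ W + b)
    return (a @ net.weights[-1] + net.biases[-1]).ravel()


def manual_lstm(net: LSTMNet, X: np.ndarray) -> np.ndarray:
    """Step-by-step evaluation of the five LSTM equations via per-gate views."""
    w = net.cell
    n, T = X.shape
    H = w.hidden
    h = np.zeros((n, H))
    c = np.zeros((n, H))
    for t in range(T):
        x = X[:, t : t + 1]
        i = sigmoid(x @ w.W_i1 + h @ w.W_i2 + w.b_i)
        o = sigmoid(x @ w.W_o1 + h @ w.W_o2 + w.b_o)
        f = sigmoid(x @ w.W_f1 + h @ w.W_f2 + w.b_f)
        c = f * c + i * np.tanh(x @ w.W_c1 + h @ w.W_c2 + w.b_c)
        h = o * np.tanh(c)
    return (h @ net.Wy + net.by).ravel()


def manual_gru(net: GRUNet, X: np.ndarray) -> np.ndarray:
    """Step-by-step evaluation of the GRU equations via per-gate views."""
    w = net.cell
    n, T = X.shape
    H = w.hidden
    h = np.zeros((n, H))
    for t in range(T):
        x = X[:, t : t + 1]
        g = sigmoid(x @ w.W_z1 + h @ w.W_z2 + w.b_z)
        r = sigmoid(x @ w.W_r1 + h @ w.W_r2 + w.b_r)
        h_cand = np.tanh(x @ w.W_h1 + (r * h) @ w.W_h2 + w.b_h)
        h = (1 - g) * h + g * h_cand
    return (h @ net.Wy + net.by).ravel()


# ---------------------------------------------------------------------------
# windows

def test_window_lengths_follow_grid_arithmetic(small_cohort):
    assert make_windows(small_cohort, 15.0).X.shape[1] == 31
    assert make_windows(small_cohort, 5.0).X.shape[1] == 11
    full = make_windows(small_cohort, 60.0, allow_any_length=True)
    assert full.X.shape[1] == 121
    np.testing.assert_array_equal(full.X[:, -1], full.y)  # degenerate: target = last input


def test_nonstandard_length_needs_flag(small_cohort):
    with pytest.raises(ValueError):
        make_windows(small_cohort, 6.0)
    assert make_windows(small_cohort, 6.0, allow_any_length=True).X.shape[1] == 13


# ---------------------------------------------------------------------------
# forward passes

def test_mlp_zero_weights_give_zero_output():
    net = build_net(ArchitectureSpec("MLP", activation="tanh"), 4, seed=0)
    for p in net.params:
        p[...] = 0.0
    assert np.all(net.forward(np.ones((3, 4))) == 0.0)


def test_mlp_identity_composition():
    net = build_net(ArchitectureSpec("MLP", hidden_sizes=(1, 1), activation="identity"), 1, seed=0)
    for W in net.weights:
        W[...] = 1.0
    for b in net.biases:
        b[...] = 0.0
    assert net.forward(np.array([[2.0]]))[0] == pytest.approx(2.0)


def test_lstm_zero_weights_keep_state_at_zero():
    net = build_net(ArchitectureSpec("LSTM", hidden_sizes=(3,)), 5, seed=0)
    for p in net.params:
        p[...] = 0.0
    st = lstm_step(LSTMState(h=np.zeros((1, 3)), c=np.zeros((1, 3))), net.cell, np.array([[0.7]]))
    np.testing.assert_allclose(st.i, 0.5)
    np.testing.assert_allclose(st.o, 0.5)
    np.testing.assert_allclose(st.f, 0.5)
    np.testing.assert_allclose(st.c, 0.0)
    np.testing.assert_allclose(st.h, 0.0)


def test_lstm_gates_stay_strictly_inside_unit_interval(rng):
    net = build_net(ArchitectureSpec("LSTM", hidden_sizes=(4,)), 3, seed=2)
    st = LSTMState(h=rng.normal(size=(2, 4)), c=rng.normal(size=(2, 4)))
    nxt = lstm_step(st, net.cell, rng.normal(size=(2, 1)))
    for gate in (nxt.i, nxt.o, nxt.f):
        assert np.all((gate > 0) & (gate < 1))


def test_lstm_two_steps_match_manual_arithmetic(rng):
    """Unit-dimension cell, hand-evaluated against the gate equations."""
    net = build_net(ArchitectureSpec("LSTM", hidden_sizes=(1,)), 2, seed=3)
    w = net.cell
    x = rng.normal(size=(1, 2))
    # manual scalar evaluation, two steps
    h = c = 0.0
    for t in range(2):
        xt = x[0, t]
        i = sigmoid(xt * w.W_i1[0, 0] + h * w.W_i2[0, 0] + w.b_i[0])
        o = sigmoid(xt * w.W_o1[0, 0] + h * w.W_o2[0, 0] + w.b_o[0])
        f = sigmoid(xt * w.W_f1[0, 0] + h * w.W_f2[0, 0] + w.b_f[0])
        c = f * c + i * np.tanh(xt * w.W_c1[0, 0] + h * w.W_c2[0, 0] + w.b_c[0])
        h = o * np.tanh(c)
    expected = h * net.Wy[0, 0] + net.by[0]
    assert net.forward(x)[0] == pytest.approx(expected, abs=1e-12)


def test_gru_zero_weights_keep_hidden_at_zero():
    net = build_net(ArchitectureSpec("GRU", hidden_sizes=(3,)), 4, seed=0)
    for p in net.params:
        p[...] = 0.0
    st = gru_step(GRUState(h=np.zeros((1, 3))), net.cell, np.array([[0.9]]))
    np.testing.assert_allclose(st.g, 0.5)
    np.testing.assert_allclose(st.r, 0.5)
    np.testing.assert_allclose(st.h, 0.0)


def test_gru_saturated_update_gate_copies_candidate(rng):
    net = build_net(ArchitectureSpec("GRU", hidden_sizes=(3,)), 2, seed=1)
    net.cell.b_gr[:3] = 50.0  # update-gate bias -> g ~ 1
    h = rng.normal(size=(1, 3))
    st = gru_step(GRUState(h=h), net.cell, rng.normal(size=(1, 1)))
    np.testing.assert_allclose(st.h, st.h_cand, atol=1e-10)


def test_gru_two_steps_match_manual_arithmetic(rng):
    net = build_net(ArchitectureSpec("GRU", hidden_sizes=(1,)), 2, seed=5)
    w = net.cell
    x = rng.normal(size=(1, 2))
    h = 0.0
    for t in range(2):
        xt = x[0, t]
        g = sigmoid(xt * w.W_z1[0, 0] + h * w.W_z2[0, 0] + w.b_z[0])
        r = sigmoid(xt * w.W_r1[0, 0] + h * w.W_r2[0, 0] + w.b_r[0])
        h_cand = np.tanh(xt * w.W_h1[0, 0] + (r * h) * w.W_h2[0, 0] + w.b_h[0])
        h = (1 - g) * h + g * h_cand
    expected = h * net.Wy[0, 0] + net.by[0]
    assert net.forward(x)[0] == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("kind", ["MLP", "LSTM", "GRU"])
def test_forward_matches_independent_recomputation(kind, rng):
    """Batch forward equals the hand-rolled matrix-arithmetic oracle, 200 draws."""
    oracles = {"MLP": manual_mlp, "LSTM": manual_lstm, "GRU": manual_gru}
    for trial in range(200):
        hidden = (3, 2) if kind == "MLP" else (int(rng.integers(1, 5)),)
        net = build_net(ArchitectureSpec(kind, hidden_sizes=hidden), 4, seed=trial)
        X = rng.normal(size=(3, 4))
        np.testing.assert_allclose(net.forward(X), oracles[kind](net, X), atol=1e-10)


@pytest.mark.parametrize("kind", ["MLP", "LSTM", "GRU"])
def test_backprop_matches_finite_differences(kind, rng):
    spec = ArchitectureSpec(kind, hidden_sizes=(4, 3) if kind == "MLP" else (4,),
                            activation="tanh" if kind == "MLP" else "relu")
    net = build_net(spec, 5, seed=9)
    X = rng.normal(size=(6, 5))
    y = rng.normal(size=6)
    _, grads = net.loss_grads(X, y)
    eps = 1e-6
    for p, g in zip(net.params, grads):
        flat_idx = np.unravel_index(rng.integers(p.size), p.shape)  # spot-check each array
        orig = p[flat_idx]
        p[flat_idx] = orig + eps
        lp, _ = net.loss_grads(X, y)
        p[flat_idx] = orig - eps
        lm, _ = net.loss_grads(X, y)
        p[flat_idx] = orig
        assert (lp - lm) / (2 * eps) == pytest.approx(g[flat_idx], rel=1e-4, abs=1e-8)


# ---------------------------------------------------------------------------
# training

def _tiny_windows(n, T, seed, y=None):
    rng = np.random.default_rng(seed)
    X = rng.uniform(0.4, 1.0, size=(n, T))
    y = rng.uniform(0.35, 0.86, size=n) if y is None else y
    return WindowSet(X, y, [f"s{i}" for i in range(n)], length_min=(T - 1) * 0.5)


def test_training_is_deterministic_under_fixed_seed():
    train = _tiny_windows(20, 11, 0)
    val = _tiny_windows(6, 11, 1)
    cfg = TrainConfig(max_epochs=30, patience=5, seed=7)
    m1 = train_model(ArchitectureSpec("GRU"), cfg, train, val)
    m2 = train_model(ArchitectureSpec("GRU"), cfg, train, val)
    for p1, p2 in zip(m1.net.params, m2.net.params):
        np.testing.assert_array_equal(p1, p2)
    assert m1.log.equals(m2.log)


def test_early_stopping_triggers_after_patience_epochs():
    """Val targets opposite to train targets: val loss worsens every epoch."""
    train = _tiny_windows(8, 5, 0, y=np.full(8, 0.9))
    val = _tiny_windows(4, 5, 1, y=np.full(4, -5.0))
    cfg = TrainConfig(max_epochs=300, patience=15, seed=0)
    model = train_model(ArchitectureSpec("MLP"), cfg, train, val)
    assert model.best_epoch == 1
    assert len(model.log) == 1 + 15


def test_training_rejects_empty_sets():
    good = _tiny_windows(5, 5, 0)
    empty = WindowSet(np.empty((0, 5)), np.empty(0), [], length_min=2.0)
    with pytest.raises(TrainingError):
        train_model(ArchitectureSpec("MLP"), TrainConfig(), empty, good)


def test_learned_model_beats_constant_mean_predictor():
    """GRU on 200 synthetic curves at L=15 outperforms the train-mean baseline."""
    curves = generate_dataset(200, 0, seed=21)
    tr, va, te = split_cohort(curves, seed=0)
    w = lambda cs: make_windows(cs, 15.0)
    model = train_model(ArchitectureSpec("GRU"), TrainConfig(seed=0), w(tr), w(va))
    test = w(te)
    model_mape = mape(test.y, predict(model, test))
    baseline_mape = mape(test.y, np.full(test.n, w(tr).y.mean()))
    assert model_mape < baseline_mape


def test_predict_zeroed_output_layer_returns_bias():
    train = _tiny_windows(10, 5, 0)
    model = train_model(ArchitectureSpec("MLP"), TrainConfig(max_epochs=5, patience=2, seed=0),
                        train, _tiny_windows(4, 5, 1))
    model.net.weights[-1][...] = 0.0
    model.net.biases[-1][...] = 0.123
    np.testing.assert_allclose(predict(model, train), 0.123)


def test_predict_preserves_sample_order():
    train = _tiny_windows(10, 5, 0)
    model = train_model(ArchitectureSpec("MLP"), TrainConfig(max_epochs=5, patience=2, seed=0),
                        train, _tiny_windows(4, 5, 1))
    pred = predict(model, train.X)
    perm = np.random.default_rng(0).permutation(10)
    np.testing.assert_allclose(predict(model, train.X[perm]), pred[perm], atol=1e-12)


def test_predict_rejects_wrong_window_length():
    train = _tiny_windows(10, 5, 0)
    model = train_model(ArchitectureSpec("MLP"), TrainConfig(max_epochs=5, patience=2, seed=0),
                        train, _tiny_windows(4, 5, 1))
    with pytest.raises(ValueError):
        predict(model, np.ones((2, 7)))


def test_overfit_capacity_on_tiny_set():
    """A small MLP memorizes 3 samples: train MSE below 1e-3."""
    train = _tiny_windows(3, 5, 0)
    cfg = TrainConfig(max_epochs=299, patience=250, seed=1)
    model = train_model(ArchitectureSpec("MLP"), cfg, train, train)
    pred = predict(model, train)
    assert np.mean((pred - train.y) ** 2) < 1e-3


def test_weight_dump_uses_standard_gate_names():
    train = _tiny_windows(8, 5, 0)
    val = _tiny_windows(3, 5, 1)
    cfg = TrainConfig(max_epochs=3, patience=2, seed=0)
    lstm = train_model(ArchitectureSpec("LSTM"), cfg, train, val)
    d = weights_to_dict(lstm)
    assert {"W_i1", "W_i2", "b_i", "W_f1", "W_c2", "W_y"} <= set(d)
    assert np.array(d["W_i2"]).shape == (15, 15)
    gru = train_model(ArchitectureSpec("GRU"), cfg, train, val)
    d2 = weights_to_dict(gru)
    assert {"W_z1", "W_r2", "b_h", "W_h2"} <= set(d2)
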