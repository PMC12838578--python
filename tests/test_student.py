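"""Student network: each block checked against hand-computed values, plus
the causal streaming contract."""

import math

import numpy as np
import pytest

from seizkd import nn
from seizkd.autodiff import Tensor, no_grad
from seizkd.student import (StreamState, StudentConfig, StudentModel,
                            count_parameters, load_student, save_checkpoint,
                            sfpm_update)


@pytest.fixture(scope="module")
def model():
    return StudentModel(StudentConfig(), seed=1)


# --------------------------------------------------------------- conv front end


def test_channel_expansion_hand_example():
    """1x1 expansion on a single time step: X=(1,2), identity weights, no
    bias -> U=(1,2)."""
    rng = np.random.default_rng(0)
    lin = nn.Linear(2, 2, rng)
    lin.weight.data = np.eye(2, dtype=np.float32)
    lin.bias.data = np.zeros(2, np.float32)
    u = lin(Tensor(np.array([[[1.0, 2.0]]], np.float32)))
    assert np.allclose(u.data, [[[1.0, 2.0]]])


def test_conv_front_end_zero_input_zero_bias_gives_zeros(model):
    x = Tensor(np.zeros((2, 512, model.cfg.n_channels), np.float32))
    out = model.conv_front_end(x)
    assert np.allclose(out.data, 0.0)  # biases are zero-initialised


def test_conv_front_end_output_shape_preserves_time(model):
    rng = np.random.default_rng(3)
    x = Tensor(rng.normal(size=(2, 512, 22)).astype(np.float32))
    out = model.conv_front_end(x)
    assert out.shape == (2, 512, 32)


# --------------------------------------------------------------- transformer


def test_attention_rows_sum_to_one(model, random_windows):
    x = model.conv_front_end(
        Tensor(np.swapaxes(random_windows[:2], 1, 2)))
    tokens = nn.avg_pool_tokens(x, model.cfg.stride)
    tokens = model.token_proj(tokens) + Tensor(model._posenc)
    attn = model.layers[0].attn.attention_weights(model.layers[0].ln1(tokens))
    assert np.allclose(attn.sum(axis=-1), 1.0, atol=1e-6)


def test_single_token_attention_is_identity_weight():
    rng = np.random.default_rng(0)
    mha = nn.MultiHeadSelfAttention(4, 1, rng)
    x = Tensor(rng.normal(size=(1, 1, 4)).astype(np.float32))
    assert np.allclose(mha.attention_weights(x), 1.0)


def test_two_token_attention_hand_example():
    """d=1 toy: Q=(1,0), K=(1,0), V=(2,4) -> row 1 of A is
    (e/(e+1), 1/(e+1)) and O_1 = 2e/(e+1) + 4/(e+1)."""
    q = np.array([[1.0], [0.0]])
    k = np.array([[1.0], [0.0]])
    v = np.array([[2.0], [4.0]])
    s = q @ k.T / math.sqrt(1)
    a = np.exp(s) / np.exp(s).sum(axis=1, keepdims=True)
    e = math.e
    assert np.allclose(a[0], [e / (e + 1), 1 / (e + 1)])
    o = a @ v
    assert o[0, 0] == pytest.approx(2 * e / (e + 1) + 4 / (e + 1))
    # the library softmax reproduces the same row
    lib = nn.softmax(Tensor(s.astype(np.float32)), axis=-1).data
    assert np.allclose(lib, a, atol=1e-6)


def test_token_count_equal_across_sampling_rates():
    for fs in (256.0, 512.0):
        cfg = StudentConfig(fs=fs)
        assert cfg.window_samples // cfg.stride == 64


# --------------------------------------------------------------- GRU


def test_gru_zero_weights_halves_previous_state():
    rng = np.random.default_rng(0)
    cell = nn.GRUCell(3, 3, rng)
    for p in cell.parameters():
        p.data = np.zeros_like(p.data)
    v = np.array([[0.2, -0.4, 1.0]], np.float32)
    h = cell(Tensor(np.zeros((1, 3), np.float32)), Tensor(v))
    assert np.allclose(h.data, 0.5 * v, atol=1e-6)


@pytest.mark.parametrize("bias,expect_prev", [(30.0, True), (-30.0, False)])
def test_gru_update_gate_limits(bias, expect_prev):
    rng = np.random.default_rng(0)
    cell = nn.GRUCell(2, 2, rng)
    for p in cell.parameters():
        p.data = np.zeros_like(p.data)
    cell.bz.data[:] = bias
    v = np.array([[0.8, -0.6]], np.float32)
    h = cell(Tensor(np.ones((1, 2), np.float32)), Tensor(v))
    if expect_prev:
        assert np.allclose(h.data, v, atol=1e-6)   # z -> 1: memory hold
    else:
        assert np.allclose(h.data, 0.0, atol=1e-6)  # z -> 0: candidate (tanh(0))


# --------------------------------------------------------------- ring buffer


def _push(cfg, state, scalar):
    from seizkd.student import ring_update

    h = np.full((1, cfg.gru_hidden), scalar, np.float32)
    return ring_update(state, h)


def test_ring_buffer_fifo_and_uniform_mean():
    cfg = StudentConfig(buffer_len=3)
    state = StreamState.fresh(cfg)
    for v in (1.0, 2.0, 3.0, 4.0):
        state, summary = _push(cfg, state, v)
    assert sorted(state.buffer[0, :, 0].tolist()) == [2.0, 3.0, 4.0]
    assert summary[0, 0] == pytest.approx(3.0)


def test_ring_buffer_cold_start_fill():
    state = StreamState.fresh(StudentConfig(buffer_len=5))
    _, summary = _push(StudentConfig(buffer_len=5), state, 7.0)
    assert np.allclose(summary, 7.0)


def test_ring_buffer_length_one_tracks_latest():
    cfg = StudentConfig(buffer_len=1)
    state = StreamState.fresh(cfg)
    for v in (1.0, 9.0):
        state, summary = _push(cfg, state, v)
    assert np.allclose(summary, 9.0)


def test_ring_buffer_pointer_wraps_modulo_length():
    cfg = StudentConfig(buffer_len=3)
    state = StreamState.fresh(cfg)
    pointers = []
    for v in range(5):
        state, _ = _push(cfg, state, float(v))
        pointers.append(state.pointer)
    assert pointers == [1, 2, 0, 1, 2]


# --------------------------------------------------------------- SFPM


def test_sfpm_limits_and_hand_value():
    assert sfpm_update(0.3, 0.9, 1.0) == pytest.approx(0.3)   # lam=1 freezes
    assert sfpm_update(0.3, 0.9, 0.0) == pytest.approx(0.9)   # lam=0 copies
    assert sfpm_update(0.5, 1.0, 0.9) == pytest.approx(0.55)  # 0.9*0.5+0.1*1
    assert sfpm_update(1.5, 1.0, 0.5) <= 1.0                   # clipped


def test_sfpm_equals_detection_probability_when_lambda_zero(random_windows):
    model = StudentModel(StudentConfig(sfpm_lambda=0.0), seed=2)
    state = StreamState.fresh(model.cfg)
    for i in range(3):
        state, out = model.stream_step(state, random_windows[i])
        assert out.s[0] == pytest.approx(out.y_det[0], abs=1e-6)


# --------------------------------------------------------------- FiLM + heads


def test_film_starts_as_exact_identity(model):
    """Zero-initialised generators: both branch features equal the summary."""
    rng = np.random.default_rng(4)
    f = Tensor(rng.normal(size=(3, model.cfg.d_model)).astype(np.float32))
    state = StreamState.fresh(model.cfg, batch=3)
    with no_grad():
        _, out = model.recurrent_step(f, state)
    h = model.gru(f, Tensor(np.zeros((3, model.cfg.gru_hidden), np.float32)))
    assert np.allclose(out.det_feature.data, h.data, atol=1e-6)
    assert np.allclose(out.pred_feature.data, h.data, atol=1e-6)


def test_film_hand_modulation():
    # h=0.5 with gamma=2, beta=1 -> 2*0.5 + 1 = 2.0 (direct affine form)
    assert 2.0 * 0.5 + 1.0 == pytest.approx(2.0)
    # (1+gamma) conditioning form with gamma=0, beta=0 is the identity
    h = np.array([0.3, -0.7])
    assert np.allclose((1 + 0.0) * h + 0.0, h)


def test_heads_softmax_arithmetic():
    rng = np.random.default_rng(0)
    head = nn.Linear(4, 2, rng, zero_init=True)
    p = nn.softmax(head(Tensor(np.ones((1, 4), np.float32)))).data
    assert np.allclose(p, 0.5)  # zero weights -> symmetric logits
    assert np.allclose(nn.softmax(Tensor(np.array([[3.3, 3.3]], np.float32))).data, 0.5)
    p = nn.softmax(Tensor(np.array([[math.log(3.0), 0.0]], np.float32))).data
    assert p[0, 0] == pytest.approx(0.75, abs=1e-6)


# --------------------------------------------------------------- streaming


def test_stream_outputs_do_not_depend_on_future_windows(model, random_windows):
    s1 = StreamState.fresh(model.cfg)
    outs1 = []
    for i in range(2):
        s1, o = model.stream_step(s1, random_windows[i])
        outs1.append((o.y_det.copy(), o.y_pred.copy()))
    s2 = StreamState.fresh(model.cfg)
    outs2 = []
    for i in range(3):  # an extra third window appended
        s2, o = model.stream_step(s2, random_windows[i])
        outs2.append((o.y_det.copy(), o.y_pred.copy()))
    for (d1, p1), (d2, p2) in zip(outs1, outs2[:2]):
        assert np.array_equal(d1, d2) and np.array_equal(p1, p2)


def test_step_counter_and_warm_up_flag(model, random_windows):
    state = StreamState.fresh(model.cfg)
    L = model.cfg.buffer_len
    flags = []
    for i in range(L + 2):
        state, out = model.stream_step(state, random_windows[i % len(random_windows)])
        assert state.step == i + 1
        flags.append(out.warm_up)
    assert all(flags[:L]) and not any(flags[L:])


def test_batched_step_matches_sequential_loop(model, random_windows):
    with no_grad():
        feats = model.encode_windows(random_windows[:6])
    fd = feats.data.reshape(1, 6, model.cfg.d_model)
    state = StreamState.fresh(model.cfg)
    _, consts = model.unroll_constants(fd, state)
    with no_grad():
        batched = model.batched_step(feats, {k: v.reshape(6, -1)
                                             for k, v in consts.items()})
    state = StreamState.fresh(model.cfg)
    for t in range(6):
        state, out = model.stream_step(state, random_windows[t])
        assert np.allclose(batched.logits_det.data[t], out.logits_det.data[0],
                           atol=1e-5)
        assert np.allclose(batched.logits_pred.data[t], out.logits_pred.data[0],
                           atol=1e-5)


def test_stream_state_size_is_constant(model, random_windows):
    state = StreamState.fresh(model.cfg)
    sizes = []
    for i in range(4):
        state, _ = model.stream_step(state, random_windows[i])
        sizes.append(state.buffer.nbytes + state.h.nbytes)
    assert len(set(sizes)) == 1


def test_shape_mismatch_raises(model):
    with pytest.raises(ValueError, match="window shape"):
        model.encode_windows(np.zeros((1, 3, 512), np.float32))


# --------------------------------------------------------------- parameters


def test_parameter_count_in_published_band():
    n = count_parameters(StudentConfig())
    assert 60_000 <= n <= 90_000
    assert 0.24 <= n * 4 / 1e6 <= 0.36  # 32-bit weight archive, MB


def test_parameter_count_monotone_in_gru_width():
    small = count_parameters(StudentConfig(gru_hidden=32))
    big = count_parameters(StudentConfig(gru_hidden=64))
    assert big > small


def test_parameter_count_matches_independent_enumeration(model):
    total = sum(arr.size for arr in model.state_dict().values())
    assert total == model.n_parameters() == count_parameters(model.cfg)


# --------------------------------------------------------------- checkpoints


def test_checkpoint_round_trip(tmp_path, model, random_windows):
    path = tmp_path / "student.npz"
    save_checkpoint(model, path)
    clone = load_student(path)
    s1 = StreamState.fresh(model.cfg)
    s2 = StreamState.fresh(clone.cfg)
    _, o1 = model.stream_step(s1, random_windows[0])
    _, o2 = clone.stream_step(s2, random_windows[0])
    assert np.array_equal(o1.y_det, o2.y_det)
    assert np.array_equal(o1.y_pred, o2.y_pred)


def test_prior_pathway_carries_no_gradient_to_detection_head(model,
                                                             random_windows):
    """A prediction-only loss must leave the detection head untouched: the
    SFPM prior enters the prediction branch as a constant."""
    feats = model.encode_windows(random_windows[:4])
    state = StreamState.fresh(model.cfg, batch=4)
    _, out = model.recurrent_step(feats, state)
    loss = nn.cross_entropy(out.logits_pred, np.array([0, 1, 0, 1]))
    model.zero_grad()
    loss.backward()
    assert model.head_det.weight.grad is None
    assert model.head_pred.weight.grad is not None
    assert model.film_det.fc2.weight.grad is None
    assert model.film_pred.fc2.weight.grad is not None
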