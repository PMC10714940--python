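"""Model-core contracts: bilinear sampling, deformable convolution vs the
brute-force kernel-sum oracle, backbone geometry, LSTM/attention/classifier
vs scalar-loop references, variant wiring, checkpointing."""

import numpy as np
import pytest

from oracles import (attention_ref, bilinear_ref, bilstm_ref, classify_ref,
                     deform_conv_ref, lstm_params_to_ref, lstm_step_ref,
                     run_lstm_ref)
from stressnet._autodiff import Tensor
from stressnet.model_core import (LSTMParams, LSTMState, StressNet,
                                  attention_pool, backbone_config,
                                  bilinear_sample, bilstm_forward,
                                  build_backbone, classify, deformable_conv,
                                  lstm_step, predict_offsets, resolve_variant,
                                  stressnet_forward)


# ---------------------------------------------------------------------------
# bilinear sampling
# ---------------------------------------------------------------------------

def test_bilinear_examples():
    fm = [[1.0, 2.0], [3.0, 4.0]]
    assert bilinear_sample(fm, (0, 1)) == 2.0
    assert bilinear_sample(fm, (0.5, 0.5)) == 2.5
    assert bilinear_sample(fm, (-5, -5)) == 0.0


def test_bilinear_reproduces_grid_and_is_linear_within_cell(rng):
    fm = rng.normal(size=(5, 6))
    for i in range(5):
        for j in range(6):
            assert bilinear_sample(fm, (i, j)) == pytest.approx(fm[i, j])
    # linearity in location inside one cell: f(a*p + (1-a)*q) interpolates
    p, q = (1.2, 2.3), (1.9, 2.3)       # same cell, along one axis
    for a in (0.0, 0.25, 0.5, 1.0):
        loc = (a * p[0] + (1 - a) * q[0], 2.3)
        expect = a * bilinear_sample(fm, p) + (1 - a) * bilinear_sample(fm, q)
        assert bilinear_sample(fm, loc) == pytest.approx(expect, abs=1e-12)


def test_bilinear_matches_scalar_reference(rng):
    fm = rng.normal(size=(4, 4))
    for loc in [(0.3, 2.7), (-0.4, 1.1), (3.6, 3.6), (2.0, 0.5)]:
        assert bilinear_sample(fm, loc) == pytest.approx(
            bilinear_ref(fm, *loc), abs=1e-12)


# ---------------------------------------------------------------------------
# deformable convolution
# ---------------------------------------------------------------------------

def test_zero_offsets_reduce_to_standard_convolution(rng):
    from stressnet._autodiff import conv2d
    x = rng.normal(size=(1, 3, 8, 8))
    w = rng.normal(size=(4, 3, 3, 3))
    b = rng.normal(size=4)
    off = np.zeros((1, 18, 8, 8))
    got = deformable_conv(x, w, b, off, stride=1, padding=1)
    ref = conv2d(Tensor(x), Tensor(w), Tensor(b), 1, 1).data
    assert np.abs(got - ref).max() < 1e-5


def test_constant_field_invariance_under_small_offsets(rng):
    """On a constant input, interior outputs of an all-ones 3x3 kernel equal
    9v whenever every displaced tap stays strictly inside the map."""
    v = 0.7
    x = np.full((1, 6, 6), v)
    w = np.ones((1, 1, 3, 3))
    off = rng.uniform(-0.4, 0.4, size=(18, 4, 4))
    out = deformable_conv(x, w, None, off, stride=1, padding=0)
    # interior outputs: every displaced tap stays strictly inside the map
    assert np.allclose(out[:, 1:-1, 1:-1], 9 * v, atol=1e-10)


def test_fractional_offsets_match_brute_force_oracle(rng):
    x = np.arange(16, dtype=np.float64).reshape(1, 4, 4)
    w = rng.normal(size=(2, 1, 3, 3))
    b = rng.normal(size=2)
    off = np.zeros((18, 4, 4))
    off[0, 2, 1] = 0.5                       # single-tap fractional offset
    got = deformable_conv(x, w, b, off, stride=1, padding=1)
    ref = deform_conv_ref(x, w, b, off, stride=1, padding=1)
    assert np.abs(got - ref).max() < 1e-10


@pytest.mark.parametrize("stride,padding", [(1, 0), (1, 1), (2, 1)])
def test_random_offsets_match_brute_force_oracle(stride, padding, rng):
    x = rng.normal(size=(2, 6, 6))
    w = rng.normal(size=(3, 2, 3, 3))
    OH = (6 + 2 * padding - 3) // stride + 1
    off = rng.uniform(-2, 2, size=(18, OH, OH))
    got = deformable_conv(x, w, None, off, stride=stride, padding=padding)
    ref = deform_conv_ref(x, w, None, off, stride=stride, padding=padding)
    assert np.abs(got - ref).max() < 1e-10


def test_offset_predictor_contracts(rng):
    x = rng.normal(size=(2, 8, 8))
    zero_w, zero_b = np.zeros((18, 2, 3, 3)), np.zeros(18)
    assert np.all(predict_offsets(x, zero_w, zero_b, 1, 1) == 0.0)
    bias = np.tile([0.5, 0.0], 9)
    field = predict_offsets(x, zero_w, bias, 1, 1)
    assert np.allclose(field[0::2], 0.5) and np.allclose(field[1::2], 0.0)
    w = rng.normal(size=(18, 2, 3, 3))
    assert np.array_equal(predict_offsets(x, w, zero_b, 1, 1),
                          predict_offsets(x, w, zero_b, 1, 1))


# ---------------------------------------------------------------------------
# backbones
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("name,channels,feat", [
    ("alexnet", 5, 4096),
    ("vgg16", 5, 8192),
    ("vgg16", 3, 8192),          # head size independent of input channels
])
def test_backbone_feature_lengths(name, channels, feat):
    cfg = backbone_config(name, channels)
    assert cfg.feature_length == feat
    bb = build_backbone(cfg, deformable_final=True, seed=0)
    x = Tensor(np.random.default_rng(0).uniform(size=(1, channels, 140, 140)))
    out = bb.forward(x)
    assert out.shape == (1, feat)


def test_unknown_backbone_rejected():
    with pytest.raises(ValueError):
        backbone_config("resnet18")


# ---------------------------------------------------------------------------
# LSTM
# ---------------------------------------------------------------------------

def _random_lstm(rng, din, hid):
    return LSTMParams.create(rng, din, hid)


def _zero_lstm(din, hid):
    z = lambda *s: Tensor(np.zeros(s), requires_grad=True)  # noqa: E731
    return LSTMParams(z(din, hid), z(hid, hid), z(hid),
                      z(din, hid), z(hid, hid), z(hid),
                      z(din, hid), z(hid, hid), z(hid),
                      z(din, hid), z(hid, hid), z(hid))


def test_lstm_zero_weights_closed_forms(rng):
    p = _zero_lstm(4, 3)
    x = rng.normal(size=(1, 4))
    s0 = LSTMState(Tensor(np.zeros((1, 3))), Tensor(np.zeros((1, 3))))
    s1 = lstm_step(x, s0, p)
    assert np.allclose(s1.h.data, 0) and np.allclose(s1.c.data, 0)
    # nonzero previous cell: c_t = 0.5 c, h_t = 0.5 tanh(0.5 c)
    c = np.array([[0.8, -1.2, 0.3]])
    s2 = lstm_step(x, LSTMState(Tensor(np.zeros((1, 3))), Tensor(c)), p)
    assert np.allclose(s2.c.data, 0.5 * c, atol=1e-12)
    assert np.allclose(s2.h.data, 0.5 * np.tanh(0.5 * c), atol=1e-12)


def test_lstm_step_matches_scalar_oracle(rng):
    np_rng = np.random.default_rng(17)
    p = _random_lstm(np_rng, 5, 3)
    x = rng.normal(size=5)
    h0, c0 = rng.normal(size=3), rng.normal(size=3)
    out = lstm_step(x[None], LSTMState(Tensor(h0[None]), Tensor(c0[None])), p)
    h_ref, c_ref = lstm_step_ref(x, h0, c0, lstm_params_to_ref(p))
    assert np.abs(out.h.data[0] - h_ref).max() < 1e-10
    assert np.abs(out.c.data[0] - c_ref).max() < 1e-10


def test_lstm_dimension_mismatch_rejected(rng):
    p = _random_lstm(np.random.default_rng(0), 5, 3)
    s0 = LSTMState(Tensor(np.zeros((1, 3))), Tensor(np.zeros((1, 3))))
    with pytest.raises(ValueError):
        lstm_step(rng.normal(size=(1, 4)), s0, p)


def test_bilstm_single_step_and_zero_weights(rng):
    np_rng = np.random.default_rng(3)
    p1, p2 = _random_lstm(np_rng, 4, 3), _random_lstm(np_rng, 3, 3)
    x = rng.normal(size=(1, 4))
    H = bilstm_forward(x[None], p1, p2)          # T=1
    assert H.shape == (1, 3, 1)
    s1 = lstm_step(x, LSTMState(Tensor(np.zeros((1, 3))), Tensor(np.zeros((1, 3)))), p1)
    s2 = lstm_step(s1.h, LSTMState(Tensor(np.zeros((1, 3))), Tensor(np.zeros((1, 3)))), p2)
    assert np.allclose(H.data[:, :, 0], s2.h.data, atol=1e-12)
    z1, z2 = _zero_lstm(4, 3), _zero_lstm(3, 3)
    H0 = bilstm_forward(rng.normal(size=(1, 5, 4)), z1, z2)
    assert np.all(H0.data == 0)


def test_bilstm_matches_explicit_two_loop_oracle(rng):
    np_rng = np.random.default_rng(23)
    p1, p2 = _random_lstm(np_rng, 4, 3), _random_lstm(np_rng, 3, 3)
    xs = [rng.normal(size=4) for _ in range(3)]
    H = bilstm_forward(np.stack(xs)[None], p1, p2)
    H_ref = bilstm_ref(xs, lstm_params_to_ref(p1), lstm_params_to_ref(p2), 3)
    assert np.abs(H.data[0] - H_ref).max() < 1e-10


def test_bilstm_concat_mode_shape_and_content(rng):
    np_rng = np.random.default_rng(29)
    p1, p2 = _random_lstm(np_rng, 4, 3), _random_lstm(np_rng, 4, 3)
    xs = [rng.normal(size=4) for _ in range(4)]
    H = bilstm_forward(np.stack(xs)[None], p1, p2, mode="concat")
    assert H.shape == (1, 6, 4)
    fwd = run_lstm_ref(xs, lstm_params_to_ref(p1), 3)
    bwd = run_lstm_ref(xs[::-1], lstm_params_to_ref(p2), 3)[::-1]
    for t in range(4):
        assert np.abs(H.data[0, :3, t] - fwd[t]).max() < 1e-10
        assert np.abs(H.data[0, 3:, t] - bwd[t]).max() < 1e-10


def test_bilstm_rejects_empty_sequence(rng):
    p = _random_lstm(np.random.default_rng(0), 4, 3)
    with pytest.raises(ValueError):
        bilstm_forward(np.zeros((1, 0, 4)), p, p)


# ---------------------------------------------------------------------------
# attention and head
# ---------------------------------------------------------------------------

def test_attention_singleton_and_symmetry(rng):
    h = rng.normal(size=(4, 1))
    R, alpha = attention_pool(h, rng.normal(size=4))
    assert np.allclose(alpha, [1.0])
    assert np.allclose(R, h[:, 0])
    col = rng.normal(size=4)
    H = np.tile(col[:, None], (1, 5))
    R, alpha = attention_pool(H, rng.normal(size=4))
    assert np.allclose(alpha, 0.2)
    assert np.allclose(R, col, atol=1e-12)


def test_attention_frozen_hand_computed_example():
    # z = (tanh 0 + tanh 1, tanh 2 + tanh 0) = (0.761594, 0.964028)
    H = np.array([[0.0, 2.0], [1.0, 0.0]])
    R, alpha = attention_pool(H, np.array([1.0, 1.0]))
    assert alpha == pytest.approx([0.449564, 0.550436], abs=1e-6)
    assert R == pytest.approx([1.100872, 0.449564], abs=1e-6)


def test_attention_matches_scalar_oracle_and_normalizes(rng):
    for _ in range(5):
        D, T = rng.integers(2, 6), rng.integers(1, 7)
        H = rng.normal(size=(D, T))
        w = rng.normal(size=D)
        R, alpha = attention_pool(H, w)
        R_ref, alpha_ref = attention_ref(H, w)
        assert np.abs(R - R_ref).max() < 1e-10
        assert np.abs(alpha - alpha_ref).max() < 1e-10
        assert alpha.min() >= 0 and abs(alpha.sum() - 1) < 1e-6


def test_classifier_contracts(rng):
    zeros = [Tensor(np.zeros((4, 5)), requires_grad=True),
             Tensor(np.zeros(5), requires_grad=True),
             Tensor(np.zeros((5, 3)), requires_grad=True),
             Tensor(np.zeros(3), requires_grad=True)]
    p = classify(rng.normal(size=4), *zeros)
    assert np.allclose(p.data, 1 / 3)
    w1, b1 = rng.normal(size=(4, 5)), rng.normal(size=5)
    w2, b2 = rng.normal(size=(5, 3)), rng.normal(size=3)
    r = rng.normal(size=4)
    p1 = classify(r, Tensor(w1), Tensor(b1), Tensor(w2), Tensor(b2)).data
    ref = classify_ref(r, w1, b1, w2, b2)
    assert np.abs(p1 - ref).max() < 1e-10
    # softmax shift invariance: constant added to every logit
    p2 = classify(r, Tensor(w1), Tensor(b1), Tensor(w2), Tensor(b2 + 10.0)).data
    assert np.abs(p1 - p2).max() < 1e-9


# ---------------------------------------------------------------------------
# full model
# ---------------------------------------------------------------------------

def test_forward_probabilities_and_channel_check(rng):
    m = StressNet(backbone="compact", input_channels=5, hidden_size=8,
                  head_hidden=6, variant="full", seed=0)
    x = rng.uniform(size=(2, 3, 5, 16, 16))
    p = m.predict_proba(x)
    assert p.shape == (2, 3)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
    single = stressnet_forward(x[0], m)
    assert single.shape == (3,) and abs(single.sum() - 1) < 1e-6
    with pytest.raises(ValueError):
        m.predict_proba(rng.uniform(size=(1, 3, 4, 16, 16)))


def test_variant_wiring():
    assert resolve_variant("full") == "full_deform_bilstm_attn"
    m_full = StressNet(backbone="compact", hidden_size=8, variant="full", seed=1)
    m_c1 = StressNet(backbone="compact", hidden_size=8, variant="case1", seed=1)
    m_c2 = StressNet(backbone="compact", hidden_size=8, variant="case2", seed=1)
    m_c3 = StressNet(backbone="compact", hidden_size=8, variant="case3", seed=1)

    def final_layer(m):
        return [e[1] for e in m.backbone.layers if e[0] == "conv"][-1]

    assert final_layer(m_full).deformable and final_layer(m_c3).deformable
    assert not final_layer(m_c1).deformable and not final_layer(m_c2).deformable
    assert m_full.att_w is not None and m_c2.att_w is not None
    assert m_c1.att_w is None and m_c3.att_w is None


def test_single_step_attention_degenerates_to_last_state(rng):
    """With T=1, attention pooling is the identity, so the full variant and
    the no-attention deformable variant coincide given identical weights."""
    m_full = StressNet(backbone="compact", input_channels=2, hidden_size=6,
                       variant="full", seed=5)
    m_c3 = StressNet(backbone="compact", input_channels=2, hidden_size=6,
                     variant="case3", seed=5)
    # align every shared parameter (draw order differs after the LSTMs)
    state = m_full.get_state()
    shared = m_c3.parameters()
    full_params = m_full.parameters()
    no_att = [p for p in full_params if p is not m_full.att_w]
    for tgt, src in zip(shared, no_att):
        tgt.data = src.data.copy()
    del state
    x = rng.uniform(size=(1, 1, 2, 12, 12))
    assert np.allclose(m_full.predict_proba(x), m_c3.predict_proba(x), atol=1e-10)


def test_frame_order_reversal_changes_prediction(desk_run):
    """A trained model must use temporal structure: reversing the frame
    order moves the output distribution (total variation > 0.01)."""
    model = desk_run["model"]
    x = desk_run["x_val"][:8]
    p_fwd = model.predict_proba(x)
    p_rev = model.predict_proba(x[:, ::-1].copy())
    tv = 0.5 * np.abs(p_fwd - p_rev).sum(axis=1)
    assert tv.max() > 0.01


def test_checkpoint_round_trip(tmp_path, rng):
    m = StressNet(backbone="compact", input_channels=3, hidden_size=6,
                  variant="case2", seed=9)
    x = rng.uniform(size=(1, 2, 3, 12, 12))
    p_before = m.predict_proba(x)
    path = tmp_path / "ckpt.npz"
    m.save(path)
    m2 = StressNet.load(path)
    assert m2.config == m.config
    assert np.allclose(m2.predict_proba(x), p_before, atol=1e-12)


def test_full_model_gradients_match_finite_differences(rng):
    """Finite-difference check of the training loss w.r.t. 10 randomly
    chosen parameters, explicitly including offset-predictor weights."""
    from stressnet.train_eval import _cross_entropy_tensor, one_hot
    m = StressNet(backbone="compact", input_channels=2, hidden_size=5,
                  head_hidden=4, variant="full", seed=13)
    # move the offset predictor off its zero init: bilinear sampling is
    # non-differentiable exactly at integer grid points, so the check must
    # run at a generic (fractional-offset) parameter point
    for e in m.backbone.layers:
        if e[0] == "conv" and e[1].deformable:
            e[1].off_w.data += rng.normal(0, 0.05, e[1].off_w.shape)
            e[1].off_b.data += rng.normal(0, 0.1, e[1].off_b.shape)
    x = rng.uniform(size=(2, 2, 2, 10, 10))
    y = one_hot([1, 2])
    loss = _cross_entropy_tensor(m.forward(x), y)
    for p in m.parameters():
        p.grad = None
    loss.backward()
    params = m.parameters()
    off_params = [i for i, p in enumerate(params)
                  for e in m.backbone.layers if e[0] == "conv"
                  and e[1].deformable and p is e[1].off_w]
    pick = off_params + list(rng.choice(len(params), size=9, replace=False))

    def loss_value():
        return float(_cross_entropy_tensor(m.forward(x), y).data)

    checked = 0
    for pi in pick[:10]:
        p = params[pi]
        idx = tuple(int(rng.integers(s)) for s in p.data.shape)
        eps, old = 1e-5, p.data[idx]
        p.data[idx] = old + eps
        lp = loss_value()
        p.data[idx] = old - eps
        lm = loss_value()
        p.data[idx] = old
        fd = (lp - lm) / (2 * eps)
        an = p.grad[idx]
        denom = max(abs(fd) + abs(an), 1e-8)
        assert abs(fd - an) / denom < 1e-3, f"param {pi}: fd={fd} an={an}"
        checked += 1
    assert checked == 10
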