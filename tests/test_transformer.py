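"""Transformer operators against naive attention and scalar-loop oracles."""

import numpy as np
import pytest

from dualseg.config import MTConfig
from dualseg.nn import layer_norm, to_map, to_tokens
from dualseg.transformer import (ChannelSelfAttention, EfficientSelfAttention,
                                 InteractChannel, InteractSpatial, LocalBranch,
                                 MTBlock, SpatialSelfAttention,
                                 TransformerEncoder, window_merge,
                                 window_partition)

F32 = np.float32


def naive_attention(q, k, v, scale):
    """Textbook O(N^2) scaled-dot-product attention, explicit loops."""
    n, d = q.shape
    m = k.shape[0]
    out = np.zeros((n, v.shape[1]))
    for i in range(n):
        scores = np.array([np.dot(q[i], k[j]) * scale for j in range(m)])
        e = np.exp(scores - scores.max())
        a = e / e.sum()
        for j in range(m):
            out[i] += a[j] * v[j]
    return out


# ---------------------------------------------------------------------------
# efficient self-attention
# ---------------------------------------------------------------------------

def test_esa_r1_matches_naive_oracle():
    """20 seeded random instances, max abs error <= 1e-5."""
    for seed in range(20):
        rng = np.random.default_rng(seed)
        esa = EfficientSelfAttention(np.random.default_rng(seed + 100), dim=8, reduction=1)
        p = esa.param_tree()
        x = rng.standard_normal((2, 16, 8)).astype(F32)
        y = esa.forward(p, x)
        t = layer_norm(x, p["norm"]["gamma"], p["norm"]["beta"])
        for b in range(2):
            q = t[b] @ p["wq"]["w"]
            k = t[b] @ p["wk"]["w"]
            v = t[b] @ p["wv"]["w"]
            expect = x[b] + naive_attention(q, k, v, 1 / np.sqrt(8))
            assert np.max(np.abs(np.asarray(y[b]) - expect)) <= 1e-5


def test_esa_identical_tokens_give_uniform_attention(rng):
    esa = EfficientSelfAttention(np.random.default_rng(0), dim=6, reduction=1)
    p = esa.param_tree()
    token = rng.standard_normal(6).astype(F32)
    x = np.tile(token, (1, 10, 1))
    y, attn = esa.forward(p, x, return_attn=True)
    assert np.allclose(attn, 0.1, atol=1e-6)
    delta = np.asarray(y - x)
    assert np.allclose(delta, delta[:, :1], atol=1e-6)   # token-constant update


@pytest.mark.parametrize("R", [1, 2, 4])
def test_esa_attention_storage_is_reduced(rng, R):
    esa = EfficientSelfAttention(np.random.default_rng(0), dim=4, reduction=R)
    x = rng.standard_normal((1, 8, 4)).astype(F32)
    _, attn = esa.forward(esa.param_tree(), x, return_attn=True)
    assert attn.shape == (1, 8, 8 // R)
    assert np.allclose(np.asarray(attn).sum(axis=-1), 1.0, atol=1e-6)


def test_esa_divisibility_error(rng):
    esa = EfficientSelfAttention(np.random.default_rng(0), dim=4, reduction=3)
    x = rng.standard_normal((1, 8, 4)).astype(F32)
    with pytest.raises(ValueError, match="N=8.*R=3"):
        esa.forward(esa.param_tree(), x)


# ---------------------------------------------------------------------------
# windows
# ---------------------------------------------------------------------------

def test_window_partition_merge_roundtrip(rng):
    f = rng.standard_normal((2, 3, 10, 10)).astype(F32)
    wins, meta = window_partition(f, 4)
    assert wins.shape == (2 * 9, 16, 3)       # padded to 12x12
    back = window_merge(wins, meta)
    assert np.array_equal(np.asarray(back), f)


def test_window_counting(rng):
    f = rng.standard_normal((1, 2, 8, 8)).astype(F32)
    wins, _ = window_partition(f, 4)
    assert wins.shape == (4, 16, 2)


def test_window_one_is_reshape(rng):
    f = rng.standard_normal((1, 2, 3, 5)).astype(F32)
    wins, meta = window_partition(f, 1)
    assert wins.shape == (15, 1, 2)
    assert np.array_equal(np.asarray(window_merge(wins, meta)), f)


# ---------------------------------------------------------------------------
# spatial self-attention
# ---------------------------------------------------------------------------

def test_ssa_full_window_matches_naive_oracle():
    """Single head, window covering the image, zero positional bias."""
    for seed in range(5):
        cfg = MTConfig(heads=1, window=4, r1=2, r2=2)
        ssa = SpatialSelfAttention(np.random.default_rng(seed), dim=6, cfg=cfg)
        p = ssa.param_tree()
        rng = np.random.default_rng(seed + 50)
        f = rng.standard_normal((1, 6, 4, 4)).astype(F32)
        y_sp = ssa.attention_map(p, f)
        t = layer_norm(np.asarray(to_tokens(f)), p["norm"]["gamma"], p["norm"]["beta"])[0]
        q = t @ p["wq"]["w"]
        k = t @ p["wk"]["w"]
        v = t @ p["wv"]["w"]
        expect = naive_attention(q, k, v, 1 / np.sqrt(6)) @ p["merge_heads"]["w"]
        got = np.asarray(to_tokens(y_sp))[0]
        assert np.max(np.abs(got - expect)) <= 1e-5


def test_ssa_shape_preserved_and_head_check(rng):
    cfg = MTConfig(heads=2, window=3)
    ssa = SpatialSelfAttention(np.random.default_rng(0), dim=8, cfg=cfg)
    f = rng.standard_normal((2, 8, 7, 5)).astype(F32)
    local = LocalBranch(np.random.default_rng(1), 8)
    y = ssa.forward(ssa.param_tree(), f, local.forward(local.param_tree(), f))
    assert y.shape == f.shape
    with pytest.raises(ValueError, match="heads"):
        SpatialSelfAttention(np.random.default_rng(0), dim=7, cfg=cfg)


# ---------------------------------------------------------------------------
# local branch
# ---------------------------------------------------------------------------

def test_local_branch_identity_kernel(rng):
    lb = LocalBranch(np.random.default_rng(0), 4)
    p = lb.param_tree()
    p["dw"]["w"] = np.zeros_like(p["dw"]["w"])
    p["dw"]["w"][:, 1, 1] = 1.0
    p["dw"]["b"] = np.zeros_like(p["dw"]["b"])
    f = rng.standard_normal((2, 4, 6, 6)).astype(F32)
    assert np.allclose(np.asarray(lb.forward(p, f)), f)


def test_local_branch_preserves_channels_and_interior_constants(rng):
    lb = LocalBranch(np.random.default_rng(0), 5)
    p = lb.param_tree()
    p["dw"]["w"] = np.full_like(p["dw"]["w"], 1 / 9)
    p["dw"]["b"] = np.zeros_like(p["dw"]["b"])
    f = np.full((1, 5, 8, 8), 2.0, dtype=F32)
    y = np.asarray(lb.forward(p, f))
    assert y.shape == f.shape
    assert np.allclose(y[:, :, 1:-1, 1:-1], 2.0, atol=1e-6)


# ---------------------------------------------------------------------------
# gated interactions
# ---------------------------------------------------------------------------

def test_interaction_zero_input_absorbed(rng):
    i_s = InteractSpatial(np.random.default_rng(0), 4)
    i_c = InteractChannel(np.random.default_rng(1), 4)
    x2 = rng.standard_normal((2, 4, 5, 5)).astype(F32)
    zero = np.zeros_like(x2)
    assert np.allclose(np.asarray(i_s.forward(i_s.param_tree(), zero, x2)), 0.0)
    assert np.allclose(np.asarray(i_c.forward(i_c.param_tree(), zero, x2)), 0.0)


def test_interaction_gate_ranges_and_channel_gate_constancy(rng):
    i_s = InteractSpatial(np.random.default_rng(0), 4)
    i_c = InteractChannel(np.random.default_rng(1), 4)
    x2 = rng.standard_normal((2, 4, 5, 5)).astype(F32)
    gs = np.asarray(i_s.gate(i_s.param_tree(), x2))
    gc = np.asarray(i_c.gate(i_c.param_tree(), x2))
    for g in (gs, gc):
        assert np.all(g > 0.0) and np.all(g < 1.0)
    assert gc.shape == (2, 4, 1, 1)           # spatially constant per channel
    assert gs.std(axis=(2, 3)).max() > 0      # spatially varying


def test_interaction_shape_mismatch(rng):
    i_s = InteractSpatial(np.random.default_rng(0), 4)
    a = rng.standard_normal((1, 4, 4, 4)).astype(F32)
    with pytest.raises(ValueError, match="mismatch"):
        i_s.forward(i_s.param_tree(), a, a[:, :, :2])


def test_interactions_match_scalar_loop_oracle():
    """Tiny 1x2x2x2 tensors; explicit loops over both gating equations."""
    i_s = InteractSpatial(np.random.default_rng(3), 2, ratio=1)
    i_c = InteractChannel(np.random.default_rng(4), 2, ratio=1)
    ps, pc = i_s.param_tree(), i_c.param_tree()
    rng = np.random.default_rng(9)
    x1 = rng.standard_normal((1, 2, 2, 2)).astype(F32)
    x2 = rng.standard_normal((1, 2, 2, 2)).astype(F32)

    def gelu_s(v):
        return 0.5 * v * (1 + np.tanh(np.sqrt(2 / np.pi) * (v + 0.044715 * v**3)))

    def sig(v):
        return 0.5 * (1 + np.tanh(0.5 * v))

    # spatial gate: two chained 1x1 convs at each pixel
    w1, b1 = ps["pw1"]["w"], ps["pw1"]["b"]
    w2, b2 = ps["pw2"]["w"], ps["pw2"]["b"]
    got = np.asarray(i_s.forward(ps, x1, x2))
    hid = w1.shape[0]
    for i in range(2):
        for j in range(2):
            h = [gelu_s(sum(w1[m, c, 0, 0] * x2[0, c, i, j] for c in range(2)) + b1[m])
                 for m in range(hid)]
            for c in range(2):
                gate = sig(sum(w2[c, m, 0, 0] * h[m] for m in range(hid)) + b2[c])
                assert got[0, c, i, j] == pytest.approx(x1[0, c, i, j] * gate, abs=1e-6)

    # channel gate: GAP then two FCs
    w1, b1 = pc["fc1"]["w"], pc["fc1"]["b"]
    w2, b2 = pc["fc2"]["w"], pc["fc2"]["b"]
    got = np.asarray(i_c.forward(pc, x1, x2))
    s = [x2[0, c].mean() for c in range(2)]
    h = [gelu_s(sum(s[c] * w1[c, m] for c in range(2)) + b1[m]) for m in range(w1.shape[1])]
    for c in range(2):
        gate = sig(sum(h[m] * w2[m, c] for m in range(len(h))) + b2[c])
        for i in range(2):
            for j in range(2):
                assert got[0, c, i, j] == pytest.approx(x1[0, c, i, j] * gate, abs=1e-6)


# ---------------------------------------------------------------------------
# channel self-attention
# ---------------------------------------------------------------------------

def test_csa_softmax_columns_sum_to_one(rng):
    cfg = MTConfig(heads=2, window=2)
    csa = ChannelSelfAttention(np.random.default_rng(0), dim=8, cfg=cfg)
    f = rng.standard_normal((2, 8, 4, 4)).astype(F32)
    _, attn = csa.attention_map(csa.param_tree(), f, return_attn=True)
    assert np.allclose(np.asarray(attn).sum(axis=2), 1.0, atol=1e-6)


def test_csa_large_temperature_tends_to_channel_mean(rng):
    cfg = MTConfig(heads=1, window=2)
    csa = ChannelSelfAttention(np.random.default_rng(0), dim=4, cfg=cfg)
    p = csa.param_tree()
    p["alpha"] = np.array([1e6], dtype=F32)
    f = rng.standard_normal((1, 4, 3, 3)).astype(F32)
    ymap, attn = csa.attention_map(p, f, return_attn=True)
    assert np.allclose(np.asarray(attn), 0.25, atol=1e-4)


def test_csa_matches_scalar_loop_oracle():
    """h=1, 3 channels, 4 tokens: Y = V . softmax(Q^T K / alpha)."""
    cfg = MTConfig(heads=1, window=2)
    csa = ChannelSelfAttention(np.random.default_rng(2), dim=3, cfg=cfg)
    p = csa.param_tree()
    rng = np.random.default_rng(8)
    f = rng.standard_normal((1, 3, 2, 2)).astype(F32)
    ymap = csa.attention_map(p, f)
    got = np.asarray(to_tokens(ymap))[0]                     # (4, 3)

    t = layer_norm(np.asarray(to_tokens(f)), p["norm"]["gamma"], p["norm"]["beta"])[0]
    q = t @ p["wq"]["w"]
    k = t @ p["wk"]["w"]
    v = t @ p["wv"]["w"]
    alpha = max(float(p["alpha"][0]), 1e-4)
    scores = np.zeros((3, 3))
    for c in range(3):
        for d in range(3):
            scores[c, d] = sum(q[n, c] * k[n, d] for n in range(4)) / alpha
    attn = np.zeros((3, 3))
    for d in range(3):
        e = np.exp(scores[:, d] - scores[:, d].max())
        attn[:, d] = e / e.sum()
    y = np.zeros((4, 3))
    for n in range(4):
        for d in range(3):
            y[n, d] = sum(v[n, c] * attn[c, d] for c in range(3))
    expect = y @ p["merge_heads"]["w"]
    assert np.max(np.abs(got - expect)) <= 1e-6


def test_csa_head_divisibility_error():
    with pytest.raises(ValueError, match="heads"):
        ChannelSelfAttention(np.random.default_rng(0), dim=6, cfg=MTConfig(heads=4))


# ---------------------------------------------------------------------------
# MT block / encoder
# ---------------------------------------------------------------------------

def test_mt_block_default_lambdas():
    cfg = MTConfig()
    assert cfg.lambda1 == 0.6 and cfg.lambda2 == 0.4


def test_mt_block_zero_lambdas_reduce_to_esa_path(rng):
    cfg = MTConfig(heads=2, window=2, reduction_R=1, lambda1=0.0, lambda2=0.0)
    block = MTBlock(np.random.default_rng(0), dim=8, cfg=cfg)
    block.set_training(False)
    p = block.param_tree()
    f = rng.standard_normal((1, 8, 4, 4)).astype(F32)
    y = np.asarray(block.forward(p, f))
    y_e = to_map(block._mods["esa"].forward(p["esa"], to_tokens(f)), 4, 4)
    from dualseg.nn import gelu, linear
    t = layer_norm(np.asarray(to_tokens(y_e)), p["mlp_norm"]["gamma"], p["mlp_norm"]["beta"])
    t = linear(gelu(linear(t, p["mlp1"]["w"], p["mlp1"]["b"])), p["mlp2"]["w"], p["mlp2"]["b"])
    expect = np.asarray(y_e + to_map(t, 4, 4))
    assert np.allclose(y, expect, atol=1e-6)


def test_mt_block_shape_preserving(rng):
    cfg = MTConfig(heads=2, window=3, reduction_R=2)
    block = MTBlock(np.random.default_rng(0), dim=8, cfg=cfg)
    block.set_training(False)
    f = rng.standard_normal((2, 8, 4, 6)).astype(F32)
    assert block.forward(block.param_tree(), f).shape == f.shape


def test_transformer_encoder_pyramid(rng):
    from dualseg.config import reduced_model_config
    cfg = reduced_model_config(num_classes=3)
    enc = TransformerEncoder(np.random.default_rng(0), cfg)
    enc.set_training(False)
    p = enc.param_tree()
    x = rng.standard_normal((2, 1, 64, 64)).astype(F32)
    feats = enc.forward(p, x)
    assert [f.shape for f in feats] == [(2, 16, 16, 16), (2, 32, 8, 8), (2, 64, 4, 4)]
    feats2 = enc.forward(p, x)
    for a, b in zip(feats, feats2):
        assert np.array_equal(np.asarray(a), np.asarray(b))
    with pytest.raises(ValueError, match="divisible by 16"):
        enc.forward(p, rng.standard_normal((1, 1, 40, 64)).astype(F32))
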