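"""Transformer encoder stream: efficient self-attention with key/value length
reduction, windowed spatial self-attention with relative position bias,
channel self-attention with a learnable temperature, a depth-wise local
branch, and two gated interaction operators, combined into a
multi-dimensional transformer block.

All attention operators are pre-norm (token-wise layer norm before the
projections) and shape-preserving on (B, C, H, W) feature maps.
"""

from __future__ import annotations

import math

import autograd.numpy as anp
import numpy as np

from .config import MTConfig, ModelConfig
from .nn import (Conv2d, DWConv2d, LayerNorm, Linear, Module, gelu,
                 global_avg_pool, sigmoid, softmax, to_map, to_tokens)


# ---------------------------------------------------------------------------
# efficient self-attention (reduced key/value length)
# ---------------------------------------------------------------------------

class EfficientSelfAttention(Module):
    """Single-head scaled-dot-product attention whose key and value sequences
    are shortened from N to N/R by a reshape + linear projection, cutting the
    attention matrix from N x N to N x N/R."""

    def __init__(self, rng, dim: int, reduction: int = 1):
        super().__init__()
        self.dim = dim
        self.R = reduction
        self.add_module("norm", LayerNorm(dim))
        self.add_module("wq", Linear(rng, dim, dim, bias=False))
        self.add_module("wk", Linear(rng, dim, dim, bias=False))
        self.add_module("wv", Linear(rng, dim, dim, bias=False))
        if reduction > 1:
            self.add_module("kr", Linear(rng, dim * reduction, dim))
            self.add_module("vr", Linear(rng, dim * reduction, dim))

    def forward(self, p, x, return_attn: bool = False):
        """x: tokens (B, N, C).  Returns x + attention(LN(x))."""
        B, N, C = x.shape
        if N % self.R:
            raise ValueError(f"token count N={N} not divisible by reduction R={self.R}")
        t = self._mods["norm"].forward(p["norm"], x)
        q = self._mods["wq"].forward(p["wq"], t)
        k = self._mods["wk"].forward(p["wk"], t)
        v = self._mods["wv"].forward(p["wv"], t)
        if self.R > 1:
            k = anp.reshape(k, (B, N // self.R, C * self.R))
            k = self._mods["kr"].forward(p["kr"], k)
            v = anp.reshape(v, (B, N // self.R, C * self.R))
            v = self._mods["vr"].forward(p["vr"], v)
        attn = softmax(anp.matmul(q, anp.transpose(k, (0, 2, 1))) / math.sqrt(C), axis=-1)
        out = x + anp.matmul(attn, v)
        if return_attn:
            return out, attn
        return out


# ---------------------------------------------------------------------------
# window bookkeeping
# ---------------------------------------------------------------------------

def window_partition(f, window: int):
    """(B,C,H,W) -> windows (B*nh*nw, window*window, C) plus padding meta.

    Symmetric zero padding is applied when H or W is not a multiple of the
    window edge; :func:`window_merge` inverts exactly (pad cropped)."""
    B, C, H, W = f.shape
    ph = (-H) % window
    pw = (-W) % window
    if ph or pw:
        f = anp.pad(f, ((0, 0), (0, 0), (ph // 2, ph - ph // 2),
                        (pw // 2, pw - pw // 2)), mode="constant")
    Hp, Wp = H + ph, W + pw
    nh, nw = Hp // window, Wp // window
    x = anp.reshape(f, (B, C, nh, window, nw, window))
    x = anp.transpose(x, (0, 2, 4, 3, 5, 1))          # B, nh, nw, wy, wx, C
    wins = anp.reshape(x, (B * nh * nw, window * window, C))
    meta = (B, C, H, W, ph, pw, window)
    return wins, meta


def window_merge(wins, meta):
    """Inverse of :func:`window_partition`."""
    B, C, H, W, ph, pw, window = meta
    Hp, Wp = H + ph, W + pw
    nh, nw = Hp // window, Wp // window
    x = anp.reshape(wins, (B, nh, nw, window, window, C))
    x = anp.transpose(x, (0, 5, 1, 3, 2, 4))          # B, C, nh, wy, nw, wx
    f = anp.reshape(x, (B, C, Hp, Wp))
    return f[:, :, ph // 2: ph // 2 + H, pw // 2: pw // 2 + W]


def relative_position_index(window: int):
    """(T, T) index into the (2w-1)^2 relative-offset bias table."""
    coords = np.stack(np.meshgrid(np.arange(window), np.arange(window),
                                  indexing="ij"), axis=0).reshape(2, -1)
    rel = coords[:, :, None] - coords[:, None, :]     # (2, T, T)
    rel = rel + (window - 1)
    return rel[0] * (2 * window - 1) + rel[1]


# ---------------------------------------------------------------------------
# gated interactions
# ---------------------------------------------------------------------------

class InteractSpatial(Module):
    """x1 gated by a spatially varying sigmoid computed from x2:
    x1 * sigmoid(pw2(GELU(pw1(x2))))."""

    def __init__(self, rng, channels: int, ratio: int = 8):
        super().__init__()
        hidden = max(channels // ratio, 1)
        self.add_module("pw1", Conv2d(rng, channels, hidden, k=1, pad=0))
        self.add_module("pw2", Conv2d(rng, hidden, channels, k=1, pad=0))

    def gate(self, p, x2):
        h = gelu(self._mods["pw1"].forward(p["pw1"], x2))
        return sigmoid(self._mods["pw2"].forward(p["pw2"], h))

    def forward(self, p, x1, x2):
        if x1.shape != x2.shape:
            raise ValueError(f"shape mismatch: {x1.shape} vs {x2.shape}")
        return x1 * self.gate(p, x2)


class InteractChannel(Module):
    """x1 gated by a per-channel (spatially constant) sigmoid computed from
    the global average pool of x2."""

    def __init__(self, rng, channels: int, ratio: int = 8):
        super().__init__()
        hidden = max(channels // ratio, 1)
        self.add_module("fc1", Linear(rng, channels, hidden))
        self.add_module("fc2", Linear(rng, hidden, channels))

    def gate(self, p, x2):
        s = global_avg_pool(x2)
        g = sigmoid(self._mods["fc2"].forward(p["fc2"],
                    gelu(self._mods["fc1"].forward(p["fc1"], s))))
        return g[:, :, None, None]

    def forward(self, p, x1, x2):
        if x1.shape != x2.shape:
            raise ValueError(f"shape mismatch: {x1.shape} vs {x2.shape}")
        return x1 * self.gate(p, x2)


# ---------------------------------------------------------------------------
# spatial (windowed) self-attention
# ---------------------------------------------------------------------------

class SpatialSelfAttention(Module):
    """Window-partitioned multi-head attention over spatial tokens with a
    learnable relative position bias, fused with the depth-wise local branch
    through the two gated interactions."""

    def __init__(self, rng, dim: int, cfg: MTConfig):
        super().__init__()
        if dim % cfg.heads:
            raise ValueError(f"embed dim {dim} not divisible by heads {cfg.heads}")
        self.dim = dim
        self.heads = cfg.heads
        self.window = cfg.window
        self.add_module("norm", LayerNorm(dim))
        for name in ("wq", "wk", "wv"):
            self.add_module(name, Linear(rng, dim, dim, bias=False))
        self.add_param("bias_table",
                       np.zeros(((2 * cfg.window - 1) ** 2, cfg.heads), dtype=np.float32))
        self._rel_index = relative_position_index(cfg.window)
        self.add_module("merge_heads", Linear(rng, dim, dim, bias=False))
        self.add_module("i_s", InteractSpatial(rng, dim, cfg.r1))
        self.add_module("i_c", InteractChannel(rng, dim, cfg.r2))
        self.add_module("merge_out", Conv2d(rng, dim, dim, k=1, pad=0))

    def attention_map(self, p, f):
        """Windowed multi-head attention part only (pre local-branch fusion)."""
        B, C, H, W = f.shape
        t = self._mods["norm"].forward(p["norm"], to_tokens(f))
        tmap = to_map(t, H, W)
        q, meta = window_partition(tmap, self.window)
        # project within windows (bias-free linear maps commute with the
        # zero-padded partition)
        qw = self._mods["wq"].forward(p["wq"], q)
        kw = self._mods["wk"].forward(p["wk"], q)
        vw = self._mods["wv"].forward(p["wv"], q)
        BW, T, _ = qw.shape
        h, d = self.heads, C // self.heads

        def heads_first(z):
            return anp.transpose(anp.reshape(z, (BW, T, h, d)), (0, 2, 1, 3))

        qh, kh, vh = heads_first(qw), heads_first(kw), heads_first(vw)
        bias = p["bias_table"][self._rel_index]            # (T, T, h)
        bias = anp.transpose(bias, (2, 0, 1))[None]        # (1, h, T, T)
        attn = softmax(anp.matmul(qh, anp.transpose(kh, (0, 1, 3, 2))) / math.sqrt(d)
                       + bias, axis=-1)
        y = anp.matmul(attn, vh)                           # (BW, h, T, d)
        y = anp.reshape(anp.transpose(y, (0, 2, 1, 3)), (BW, T, C))
        y = self._mods["merge_heads"].forward(p["merge_heads"], y)
        return window_merge(y, meta)

    def forward(self, p, f, local):
        y_sp = self.attention_map(p, f)
        comb = (self._mods["i_c"].forward(p["i_c"], y_sp, local)
                + self._mods["i_s"].forward(p["i_s"], local, y_sp))
        return self._mods["merge_out"].forward(p["merge_out"], comb) + f


# ---------------------------------------------------------------------------
# channel self-attention
# ---------------------------------------------------------------------------

class ChannelSelfAttention(Module):
    """Attention across channels (tokens = channels) with a learnable
    per-head temperature alpha, fused with the local branch."""

    def __init__(self, rng, dim: int, cfg: MTConfig):
        super().__init__()
        if dim % cfg.heads:
            raise ValueError(f"channel count {dim} not divisible by heads {cfg.heads}")
        self.dim = dim
        self.heads = cfg.heads
        d_head = dim // cfg.heads
        self.add_module("norm", LayerNorm(dim))
        for name in ("wq", "wk", "wv"):
            self.add_module(name, Linear(rng, dim, dim, bias=False))
        self.add_param("alpha", np.full(cfg.heads, math.sqrt(d_head), dtype=np.float32))
        self.add_module("merge_heads", Linear(rng, dim, dim, bias=False))
        self.add_module("i_s", InteractSpatial(rng, dim, cfg.r1))
        self.add_module("i_c", InteractChannel(rng, dim, cfg.r2))
        self.add_module("merge_out", Conv2d(rng, dim, dim, k=1, pad=0))

    def attention_map(self, p, f, return_attn: bool = False):
        B, C, H, W = f.shape
        t = self._mods["norm"].forward(p["norm"], to_tokens(f))     # (B, N, C)
        q = self._mods["wq"].forward(p["wq"], t)
        k = self._mods["wk"].forward(p["wk"], t)
        v = self._mods["wv"].forward(p["wv"], t)
        h, d = self.heads, C // self.heads
        N = H * W

        def split_heads(z):                                         # (B, h, N, d)
            return anp.transpose(anp.reshape(z, (B, N, h, d)), (0, 2, 1, 3))

        qh, kh, vh = split_heads(q), split_heads(k), split_heads(v)
        alpha = anp.maximum(p["alpha"], 1e-4)[None, :, None, None]
        scores = anp.einsum("bhnc,bhnd->bhcd", qh, kh) / alpha      # (B,h,dq,dk)
        attn = softmax(scores, axis=2)      # convex mixture over query-channels
        y = anp.einsum("bhnc,bhcd->bhnd", vh, attn)
        y = anp.reshape(anp.transpose(y, (0, 2, 1, 3)), (B, N, C))
        y = self._mods["merge_heads"].forward(p["merge_heads"], y)
        ymap = to_map(y, H, W)
        if return_attn:
            return ymap, attn
        return ymap

    def forward(self, p, f, local):
        y_ch = self.attention_map(p, f)
        comb = (self._mods["i_s"].forward(p["i_s"], y_ch, local)
                + self._mods["i_c"].forward(p["i_c"], local, y_ch))
        return self._mods["merge_out"].forward(p["merge_out"], comb) + f


# ---------------------------------------------------------------------------
# full multi-dimensional transformer block
# ---------------------------------------------------------------------------

class LocalBranch(Module):
    """Depth-wise 3x3 convolutional pathway supplying local inductive bias."""

    def __init__(self, rng, dim: int):
        super().__init__()
        self.add_module("dw", DWConv2d(rng, dim, k=3))

    def forward(self, p, f):
        return self._mods["dw"].forward(p["dw"], f)


class MTBlock(Module):
    """Y = Z + MLP(LN(Z)) with Z = Y_E + lambda1 * Y_S + lambda2 * Y_C."""

    def __init__(self, rng, dim: int, cfg: MTConfig):
        super().__init__()
        self.cfg = cfg
        self.dim = dim
        self.add_module("esa", EfficientSelfAttention(rng, dim, cfg.reduction_R))
        self.add_module("local", LocalBranch(rng, dim))
        self.add_module("ssa", SpatialSelfAttention(rng, dim, cfg))
        self.add_module("csa", ChannelSelfAttention(rng, dim, cfg))
        hidden = int(dim * cfg.mlp_ratio)
        self.add_module("mlp_norm", LayerNorm(dim))
        self.add_module("mlp1", Linear(rng, dim, hidden))
        self.add_module("mlp2", Linear(rng, hidden, dim))

    def forward(self, p, f):
        B, C, H, W = f.shape
        local = self._mods["local"].forward(p["local"], f)
        y_e = to_map(self._mods["esa"].forward(p["esa"], to_tokens(f)), H, W)
        z = y_e
        if self.cfg.lambda1 != 0.0:
            z = z + self.cfg.lambda1 * self._mods["ssa"].forward(p["ssa"], f, local)
        if self.cfg.lambda2 != 0.0:
            z = z + self.cfg.lambda2 * self._mods["csa"].forward(p["csa"], f, local)
        t = self._mods["mlp_norm"].forward(p["mlp_norm"], to_tokens(z))
        t = self._mods["mlp2"].forward(p["mlp2"], gelu(self._mods["mlp1"].forward(p["mlp1"], t)))
        return z + to_map(t, H, W)


class TransformerEncoder(Module):
    """Patch-embed to stride 4 then three stages of MT blocks with stride-2
    downsampling, mirroring the CNN pyramid widths."""

    def __init__(self, rng, cfg: ModelConfig):
        super().__init__()
        w0, w1, w2 = cfg.widths
        self.blocks_per_stage = cfg.mt.blocks_per_stage
        self.add_module("embed", Conv2d(rng, cfg.in_channels, w0, k=4, stride=4, pad=0))
        self.add_module("down1", Conv2d(rng, w0, w1, k=2, stride=2, pad=0))
        self.add_module("down2", Conv2d(rng, w1, w2, k=2, stride=2, pad=0))
        for s, w in enumerate((w0, w1, w2)):
            for b in range(self.blocks_per_stage):
                self.add_module(f"s{s}b{b}", MTBlock(rng, w, cfg.mt))

    def _run_stage(self, p, s, x):
        for b in range(self.blocks_per_stage):
            key = f"s{s}b{b}"
            x = self._mods[key].forward(p[key], x)
        return x

    def forward(self, p, x):
        h, w = x.shape[2], x.shape[3]
        if h % 16 or w % 16:
            raise ValueError(f"input spatial dims ({h},{w}) must be divisible by 16")
        f1 = self._run_stage(p, 0, self._mods["embed"].forward(p["embed"], x))
        f2 = self._run_stage(p, 1, self._mods["down1"].forward(p["down1"], f1))
        f3 = self._run_stage(p, 2, self._mods["down2"].forward(p["down2"], f2))
        return [f1, f2, f3]
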