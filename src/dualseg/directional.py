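"""Direction-aware interactive attention used to fuse the CNN and
Transformer encoder streams.

Four directional poolings (row average, column max, and the two
rotation-derived reversed means) are concatenated along a common length
axis, mixed by a 1x1 convolution, and re-split into two sigmoid gate
vectors ``s_h`` (per row) and ``s_w`` (per column).  Their broadcast outer
product is a rank-1 spatial attention map that recalibrates the input
pixel-wise: ``y = x * A`` with ``A(i, j) = s_h(i) * s_w(j)``.
"""

from __future__ import annotations

from typing import NamedTuple

import autograd.numpy as anp

from .config import LAConfig
from .nn import (BatchNorm2d, Conv2d, Module, bilinear_resize, hardswish,
                 relu, sigmoid)


class DirectionalDescriptors(NamedTuple):
    x_avg: object   # (B, C, H, 1) row means
    x_max: object   # (B, C, 1, W) column maxima
    x_rot1: object  # (B, C, H, 1) row means read through a 90 deg rotation
    x_rot2: object  # (B, C, 1, W) column means read through a 270 deg rotation


def directional_pool(x) -> DirectionalDescriptors:
    """The four directional pooling descriptors of a (B,C,H,W) map.

    The rotated poolings are exact 90 deg array rotations followed by a
    directional average, read back in the source frame; for any H, W they
    reduce to index-reversed row/column means.
    """
    x_avg = anp.mean(x, axis=3, keepdims=True)                 # (B,C,H,1)
    x_max = anp.max(x, axis=2, keepdims=True)                  # (B,C,1,W)
    x_rot1 = anp.mean(x[:, :, ::-1, :], axis=3, keepdims=True)  # (B,C,H,1)
    x_rot2 = anp.mean(x[:, :, :, ::-1], axis=2, keepdims=True)  # (B,C,1,W)
    return DirectionalDescriptors(x_avg, x_max, x_rot1, x_rot2)


def _as_column(seg, length):
    """Reshape a (B,C,H,1) or (B,C,1,W) descriptor to a (B,C,length,1)
    column, linearly resampling when its own length differs."""
    if seg.shape[2] == 1:
        seg = anp.transpose(seg, (0, 1, 3, 2))
    if seg.shape[2] != length:
        seg = bilinear_resize(seg, length, 1)
    return seg


class LAModule(Module):
    """Directional attention recalibration of a single feature map."""

    def __init__(self, rng, channels: int, cfg: LAConfig | None = None):
        super().__init__()
        cfg = cfg or LAConfig()
        self.act = {"relu": relu, "hardswish": hardswish}[cfg.activation]
        self.add_module("fuse", Conv2d(rng, 4 * channels, channels, k=1, pad=0, bias=False))
        self.add_module("bn", BatchNorm2d(channels))
        self.add_module("conv_h", Conv2d(rng, channels, channels, k=1, pad=0))
        self.add_module("conv_w", Conv2d(rng, channels, channels, k=1, pad=0))

    def gates(self, p, x):
        B, C, H, W = x.shape
        L = max(H, W)
        d = directional_pool(x)
        stack = anp.concatenate([_as_column(s, L) for s in d], axis=1)  # (B,4C,L,1)
        f = self._mods["fuse"].forward(p["fuse"], stack)
        f = self.act(self._mods["bn"].forward(p["bn"], f))              # (B,C,L,1)
        fh = bilinear_resize(f, H, 1)
        fw = bilinear_resize(f, W, 1)
        s_h = sigmoid(self._mods["conv_h"].forward(p["conv_h"], fh))    # (B,C,H,1)
        s_w = sigmoid(self._mods["conv_w"].forward(p["conv_w"], fw))    # (B,C,W,1)
        s_w = anp.transpose(s_w, (0, 1, 3, 2))                          # (B,C,1,W)
        return s_h, s_w

    def forward(self, p, x):
        s_h, s_w = self.gates(p, x)
        attention = s_h * s_w            # rank-1 broadcast outer product
        return x * attention


class LAFuse(Module):
    """Fuse two identically shaped branch maps: channel concat -> 1x1
    projection back to the stage width -> directional attention."""

    def __init__(self, rng, channels: int, cfg: LAConfig | None = None):
        super().__init__()
        self.add_module("proj", Conv2d(rng, 2 * channels, channels, k=1, pad=0, bias=False))
        self.add_module("la", LAModule(rng, channels, cfg))

    def forward(self, p, f_cnn, f_trans):
        if f_cnn.shape != f_trans.shape:
            raise ValueError(f"branch shape mismatch: {f_cnn.shape} vs {f_trans.shape}")
        fused = self._mods["proj"].forward(
            p["proj"], anp.concatenate([f_cnn, f_trans], axis=1))
        return self._mods["la"].forward(p["la"], fused)
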