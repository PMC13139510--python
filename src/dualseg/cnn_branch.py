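"""CNN encoder stream: deep-split convolution blocks with branch-fusion
attention, stacked into a three-stage pyramid at strides 4 / 8 / 16.

Each stage splits its input into ``split_k`` channel groups, refines every
group with strided conv+BN+ReLU blocks, reweights the groups with a softmax
fusion attention (selective-kernel style), passes the fused map through a
bank of squeeze-excitation channel gates, and projects the concatenated
saliency maps back to the stage width with a 1x1 convolution.
"""

from __future__ import annotations

import autograd.numpy as anp
import numpy as np

from . import nn
from .config import DSMConfig, ModelConfig
from .nn import (ConvBNAct, Linear, Module, gelu, global_avg_pool, sigmoid,
                 softmax)


def split_input(x, k: int):
    """Split (B,C,H,W) into k equal channel groups.

    Concatenating the returned branches along channels reproduces ``x``
    exactly.  Raises if C is not divisible by k.
    """
    c = x.shape[1]
    if c % k != 0:
        raise ValueError(f"channel count C={c} is not divisible by split count K={k}")
    step = c // k
    return [x[:, i * step:(i + 1) * step] for i in range(k)]


class FusionAttention(Module):
    """Softmax reweighting of K identically shaped branches.

    Each branch is summarized by global average pooling, scored by a shared
    two-layer bottleneck (reduce by ``ratio``, ReLU, restore), and the scores
    are normalized with a softmax across the K branches per channel.  The
    shared scoring head keeps the operator permutation-equivariant: identical
    branches receive exactly 1/K each.
    """

    def __init__(self, rng, channels: int, k: int, ratio: int = 4):
        super().__init__()
        self.k = k
        hidden = max(channels // ratio, 4)
        self.add_module("fc1", Linear(rng, channels, hidden))
        self.add_module("fc2", Linear(rng, hidden, channels))

    def forward(self, p, branches):
        if len(branches) < 2:
            raise ValueError(f"fusion attention needs K >= 2 branches, got {len(branches)}")
        shape0 = branches[0].shape
        for b in branches[1:]:
            if b.shape != shape0:
                raise ValueError(f"branch shape mismatch: {b.shape} vs {shape0}")
        # per-branch context vectors (their sum is the pooled element-wise sum)
        ctx = [global_avg_pool(b) for b in branches]                    # K x (B,C)
        # GELU (not ReLU) in the bottleneck: a fully dead ReLU unit would
        # break the all-parameters-trainable contract at narrow widths
        logits = [self._mods["fc2"].forward(p["fc2"],
                  gelu(self._mods["fc1"].forward(p["fc1"], s))) for s in ctx]
        stacked = anp.stack(logits, axis=1)                             # (B,K,C)
        weights = softmax(stacked, axis=1)
        fused = sum(weights[:, i][:, :, None, None] * branches[i]
                    for i in range(len(branches)))
        return weights, fused


class ChannelGate(Module):
    """Squeeze-excitation channel attention: GAP -> FC -> GELU -> FC -> sigmoid."""

    def __init__(self, rng, channels: int, ratio: int = 4):
        super().__init__()
        hidden = max(channels // ratio, 4)
        self.add_module("fc1", Linear(rng, channels, hidden))
        self.add_module("fc2", Linear(rng, hidden, channels))

    def forward(self, p, x):
        s = global_avg_pool(x)
        g = sigmoid(self._mods["fc2"].forward(p["fc2"],
                    gelu(self._mods["fc1"].forward(p["fc1"], s))))
        return x * g[:, :, None, None]


class BranchConv(Module):
    """Per-branch conv+BN+ReLU stack; two stride-2 blocks in the stem stage
    (spatial /4), one elsewhere (spatial /2).  No silent padding: spatial
    dims must be divisible by the stage stride."""

    def __init__(self, rng, c_in: int, c_out: int, stem: bool):
        super().__init__()
        self.total_stride = 4 if stem else 2
        if stem:
            self.add_module("b0", ConvBNAct(rng, c_in, c_out, k=3, stride=2))
            self.add_module("b1", ConvBNAct(rng, c_out, c_out, k=3, stride=2))
        else:
            self.add_module("b0", ConvBNAct(rng, c_in, c_out, k=3, stride=2))

    def forward(self, p, x):
        h, w = x.shape[2], x.shape[3]
        if h % self.total_stride or w % self.total_stride:
            raise ValueError(
                f"spatial dims ({h},{w}) not divisible by stage stride {self.total_stride}")
        for name in self._mods:
            x = self._mods[name].forward(p[name], x)
        return x


class DSMBlock(Module):
    """One deep-split stage: channel split -> per-branch strided convs ->
    fusion attention -> bank of channel gates -> concat -> 1x1 projection."""

    def __init__(self, rng, c_in: int, c_out: int, dsm: DSMConfig, stem: bool = False):
        super().__init__()
        self.k = dsm.split_k
        self.eq3_k = dsm.eq3_k
        self.eq3_n = dsm.eq3_n
        if c_in % self.k:
            raise ValueError(f"stage input C={c_in} not divisible by split K={self.k}")
        if c_out % self.eq3_k:
            raise ValueError(f"stage width {c_out} not divisible by eq3_k={self.eq3_k}")
        for i in range(self.k):
            self.add_module(f"branch{i}", BranchConv(rng, c_in // self.k, c_out, stem))
        self.add_module("fuse", FusionAttention(rng, c_out, self.k, dsm.fusion_ratio))
        gc = c_out // self.eq3_k
        for i in range(self.eq3_k):
            for j in range(self.eq3_n):
                self.add_module(f"gate{i}_{j}", ChannelGate(rng, gc))
        self.add_module("proj", nn.Conv2d(rng, gc * self.eq3_k * self.eq3_n, c_out, k=1, pad=0))

    def forward(self, p, x):
        groups = split_input(x, self.k)
        feats = [self._mods[f"branch{i}"].forward(p[f"branch{i}"], g)
                 for i, g in enumerate(groups)]
        _, fused = self._mods["fuse"].forward(p["fuse"], feats)
        vgroups = split_input(fused, self.eq3_k)
        sal = []
        for j in range(self.eq3_n):
            for i in range(self.eq3_k):
                key = f"gate{i}_{j}"
                sal.append(self._mods[key].forward(p[key], vgroups[i]))
        cat = anp.concatenate(sal, axis=1)
        return self._mods["proj"].forward(p["proj"], cat)


class PlainStage(Module):
    """Ablation fallback (split conv disabled): ordinary conv blocks with the
    same stride/width contract as :class:`DSMBlock`."""

    def __init__(self, rng, c_in: int, c_out: int, stem: bool = False):
        super().__init__()
        self.total_stride = 4 if stem else 2
        if stem:
            self.add_module("b0", ConvBNAct(rng, c_in, c_out, k=3, stride=2))
            self.add_module("b1", ConvBNAct(rng, c_out, c_out, k=3, stride=2))
        else:
            self.add_module("b0", ConvBNAct(rng, c_in, c_out, k=3, stride=2))
            self.add_module("b1", ConvBNAct(rng, c_out, c_out, k=3, stride=1))

    def forward(self, p, x):
        h, w = x.shape[2], x.shape[3]
        if h % self.total_stride or w % self.total_stride:
            raise ValueError(
                f"spatial dims ({h},{w}) not divisible by stage stride {self.total_stride}")
        for name in self._mods:
            x = self._mods[name].forward(p[name], x)
        return x


class CNNEncoder(Module):
    """Three hierarchical stages emitting features at strides 4, 8, 16."""

    def __init__(self, rng, cfg: ModelConfig):
        super().__init__()
        w0, w1, w2 = cfg.widths
        use_dsm = cfg.toggles.use_dsm
        self.add_module("lift", ConvBNAct(rng, cfg.in_channels, w0, k=3, stride=1))
        mk = (lambda ci, co, stem: DSMBlock(rng, ci, co, cfg.dsm, stem=stem)) if use_dsm \
            else (lambda ci, co, stem: PlainStage(rng, ci, co, stem=stem))
        self.add_module("stage1", mk(w0, w0, True))
        self.add_module("stage2", mk(w0, w1, False))
        self.add_module("stage3", mk(w1, w2, False))

    def forward(self, p, x):
        h, w = x.shape[2], x.shape[3]
        if h % 16 or w % 16:
            raise ValueError(f"input spatial dims ({h},{w}) must be divisible by 16")
        x = self._mods["lift"].forward(p["lift"], x)
        f1 = self._mods["stage1"].forward(p["stage1"], x)
        f2 = self._mods["stage2"].forward(p["stage2"], f1)
        f3 = self._mods["stage3"].forward(p["stage3"], f2)
        return [f1, f2, f3]
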