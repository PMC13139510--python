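"""Full dual-branch encoder-decoder assembly.

Both encoders emit three-scale pyramids (strides 4/8/16).  At each decoder
stage the two skip maps are fused (directional attention, or a plain
concat+1x1 projection when that toggle is off), refined by two parallel
convolution paths, merged by bidirectional cross-attention (or concat when
off), and upsampled until the 1x1 head produces logits at input resolution.

Ablation toggles reproduce the module ladder: plain U-shaped CNN, +deep
split convolution, +transformer branch, +multi-scale skips, +directional
fusion, +cross-attention.
"""

from __future__ import annotations

import math

import autograd.numpy as anp
import numpy as np

from .cnn_branch import CNNEncoder
from .config import ModelConfig
from .directional import LAFuse
from .nn import (Conv2d, ConvBNAct, LayerNorm, Linear, Module,
                 bilinear_resize, softmax, to_map, to_tokens)
from .transformer import TransformerEncoder


class CrossAttentionFuse(Module):
    """Bidirectional cross-attention between two same-shape feature maps.

    Queries of each map attend keys/values of the other; the two attended
    maps are concatenated, projected back to the stage width, and a residual
    from the branch average is added.
    """

    def __init__(self, rng, dim: int, heads: int = 2):
        super().__init__()
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim = dim
        self.heads = heads
        self.add_module("norm_a", LayerNorm(dim))
        self.add_module("norm_b", LayerNorm(dim))
        for name in ("wq", "wk", "wv"):
            self.add_module(name, Linear(rng, dim, dim, bias=False))
        self.add_module("proj", Linear(rng, 2 * dim, dim))

    def _attend(self, q, k, v):
        B, N, C = q.shape
        h, d = self.heads, C // self.heads

        def hsplit(z):
            return anp.transpose(anp.reshape(z, (B, N, h, d)), (0, 2, 1, 3))

        qh, kh, vh = hsplit(q), hsplit(k), hsplit(v)
        attn = softmax(anp.matmul(qh, anp.transpose(kh, (0, 1, 3, 2))) / math.sqrt(d),
                       axis=-1)
        y = anp.matmul(attn, vh)
        return anp.reshape(anp.transpose(y, (0, 2, 1, 3)), (B, N, C))

    def forward(self, p, f_a, f_b):
        if f_a.shape != f_b.shape:
            raise ValueError(f"shape mismatch: {f_a.shape} vs {f_b.shape}")
        B, C, H, W = f_a.shape
        ta = self._mods["norm_a"].forward(p["norm_a"], to_tokens(f_a))
        tb = self._mods["norm_b"].forward(p["norm_b"], to_tokens(f_b))
        qa = self._mods["wq"].forward(p["wq"], ta)
        ka = self._mods["wk"].forward(p["wk"], ta)
        va = self._mods["wv"].forward(p["wv"], ta)
        qb = self._mods["wq"].forward(p["wq"], tb)
        kb = self._mods["wk"].forward(p["wk"], tb)
        vb = self._mods["wv"].forward(p["wv"], tb)
        y_ab = self._attend(qa, kb, vb)     # a queries b
        y_ba = self._attend(qb, ka, va)     # b queries a
        y = self._mods["proj"].forward(p["proj"], anp.concatenate([y_ab, y_ba], axis=-1))
        return to_map(y, H, W) + 0.5 * (f_a + f_b)


class ConcatFuse(Module):
    """Plain fusion fallback: channel concat + 1x1 convolution."""

    def __init__(self, rng, dim: int):
        super().__init__()
        self.add_module("proj", Conv2d(rng, 2 * dim, dim, k=1, pad=0))

    def forward(self, p, f_a, f_b):
        if f_a.shape != f_b.shape:
            raise ValueError(f"shape mismatch: {f_a.shape} vs {f_b.shape}")
        return self._mods["proj"].forward(p["proj"], anp.concatenate([f_a, f_b], axis=1))


class MultiScaleSkip(Module):
    """Resize every pyramid level to the target scale, project each to the
    target width, concatenate and fuse with a 1x1 convolution."""

    def __init__(self, rng, widths, target_idx: int):
        super().__init__()
        self.target_idx = target_idx
        self.n_levels = len(widths)
        if self.n_levels == 0:
            raise ValueError("empty encoder pyramid")
        wt = widths[target_idx]
        for i, wi in enumerate(widths):
            self.add_module(f"proj{i}", Conv2d(rng, wi, wt, k=1, pad=0))
        self.add_module("fuse", Conv2d(rng, wt * self.n_levels, wt, k=1, pad=0))

    def forward(self, p, feats):
        if not feats:
            raise ValueError("empty encoder pyramid")
        th, tw = feats[self.target_idx].shape[2], feats[self.target_idx].shape[3]
        resized = []
        for i, f in enumerate(feats):
            g = self._mods[f"proj{i}"].forward(p[f"proj{i}"], f)
            resized.append(bilinear_resize(g, th, tw))
        return self._mods["fuse"].forward(p["fuse"], anp.concatenate(resized, axis=1))


class DecoderStage(Module):
    """Upsample x2, fuse the skip pair, refine along two parallel conv paths,
    and merge them by cross-attention (or concat when disabled)."""

    def __init__(self, rng, c_prev: int, c_skip: int, cfg: ModelConfig, dual: bool):
        super().__init__()
        self.dual = dual
        self.use_ca = cfg.toggles.use_ca
        self.add_module("up", ConvBNAct(rng, c_prev, c_skip, k=3, stride=1))
        if dual:
            if cfg.toggles.use_la:
                self.add_module("skip_fuse", LAFuse(rng, c_skip, cfg.la))
            else:
                self.add_module("skip_fuse", ConcatFuse(rng, c_skip))
        self.add_module("ref_a", ConvBNAct(rng, 2 * c_skip, c_skip, k=3, stride=1))
        self.add_module("ref_b", ConvBNAct(rng, 2 * c_skip, c_skip, k=3, stride=1))
        if self.use_ca:
            self.add_module("merge", CrossAttentionFuse(rng, c_skip, cfg.ca_heads))
        else:
            self.add_module("merge", ConcatFuse(rng, c_skip))
        self.add_module("out", ConvBNAct(rng, c_skip, c_skip, k=3, stride=1))

    def forward(self, p, prev, skip_cnn, skip_trans=None):
        sh, sw = skip_cnn.shape[2], skip_cnn.shape[3]
        if prev.shape[2] * 2 != sh or prev.shape[3] * 2 != sw:
            raise ValueError(
                f"stride mismatch: prev {prev.shape[2:]} must be half of skip ({sh},{sw})")
        up = self._mods["up"].forward(p["up"], bilinear_resize(prev, sh, sw))
        if self.dual and skip_trans is not None:
            skip = self._mods["skip_fuse"].forward(p["skip_fuse"], skip_cnn, skip_trans)
        else:
            skip = skip_cnn
        cat = anp.concatenate([up, skip], axis=1)
        fa = self._mods["ref_a"].forward(p["ref_a"], cat)
        fb = self._mods["ref_b"].forward(p["ref_b"], cat)
        merged = self._mods["merge"].forward(p["merge"], fa, fb)
        return self._mods["out"].forward(p["out"], merged)


class DualBranchSegNet(Module):
    """The full segmentation network; returns logits at input resolution."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        w0, w1, w2 = cfg.widths
        t = cfg.toggles
        self.add_module("cnn", CNNEncoder(rng, cfg))
        if t.use_mt:
            self.add_module("trans", TransformerEncoder(rng, cfg))
            if t.use_la:
                self.add_module("bottleneck_fuse", LAFuse(rng, w2, cfg.la))
            else:
                self.add_module("bottleneck_fuse", ConcatFuse(rng, w2))
        if t.use_ms_skip:
            self.add_module("ms_cnn_0", MultiScaleSkip(rng, cfg.widths, 0))
            self.add_module("ms_cnn_1", MultiScaleSkip(rng, cfg.widths, 1))
            if t.use_mt:
                self.add_module("ms_trans_0", MultiScaleSkip(rng, cfg.widths, 0))
                self.add_module("ms_trans_1", MultiScaleSkip(rng, cfg.widths, 1))
        self.add_module("dec2", DecoderStage(rng, w2, w1, cfg, dual=t.use_mt))
        self.add_module("dec1", DecoderStage(rng, w1, w0, cfg, dual=t.use_mt))
        self.add_module("head", Conv2d(rng, w0, cfg.num_classes, k=1, pad=0))

    def _skips(self, p, feats, branch: str):
        if self.cfg.toggles.use_ms_skip:
            s0 = self._mods[f"ms_{branch}_0"].forward(p[f"ms_{branch}_0"], feats)
            s1 = self._mods[f"ms_{branch}_1"].forward(p[f"ms_{branch}_1"], feats)
            return s0, s1
        return feats[0], feats[1]

    def forward(self, p, image):
        if image.shape[1] != self.cfg.in_channels:
            raise ValueError(
                f"expected {self.cfg.in_channels} input channels, got {image.shape[1]}")
        H, W = image.shape[2], image.shape[3]
        if H % 16 or W % 16:
            raise ValueError(f"input spatial dims ({H},{W}) must be divisible by 16")
        cnn_feats = self._mods["cnn"].forward(p["cnn"], image)
        if self.cfg.toggles.use_mt:
            tr_feats = self._mods["trans"].forward(p["trans"], image)
            bottom = self._mods["bottleneck_fuse"].forward(
                p["bottleneck_fuse"], cnn_feats[2], tr_feats[2])
            sc0, sc1 = self._skips(p, cnn_feats, "cnn")
            st0, st1 = self._skips(p, tr_feats, "trans")
        else:
            bottom = cnn_feats[2]
            sc0, sc1 = self._skips(p, cnn_feats, "cnn")
            st0 = st1 = None
        d2 = self._mods["dec2"].forward(p["dec2"], bottom, sc1, st1)
        d1 = self._mods["dec1"].forward(p["dec1"], d2, sc0, st0)
        logits = self._mods["head"].forward(p["head"], d1)
        return bilinear_resize(logits, H, W)


def build_model(cfg: ModelConfig):
    """Construct the network and its initial parameter tree."""
    model = DualBranchSegNet(cfg)
    return model, model.param_tree()


ABLATION_LADDER = (
    ("U", dict(use_dsm=False, use_mt=False, use_ms_skip=False, use_la=False, use_ca=False)),
    ("U+D", dict(use_dsm=True, use_mt=False, use_ms_skip=False, use_la=False, use_ca=False)),
    ("U+D+M", dict(use_dsm=True, use_mt=True, use_ms_skip=False, use_la=False, use_ca=False)),
    ("U+D+M+MS", dict(use_dsm=True, use_mt=True, use_ms_skip=True, use_la=False, use_ca=False)),
    ("U+D+M+MS+L", dict(use_dsm=True, use_mt=True, use_ms_skip=True, use_la=True, use_ca=False)),
    ("full", dict(use_dsm=True, use_mt=True, use_ms_skip=True, use_la=True, use_ca=True)),
)
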