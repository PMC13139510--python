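"""Minimal neural-network layer library on numpy + autograd.

Parameters live in nested dicts of float32 arrays ("param trees") so that
``autograd.value_and_grad`` can differentiate a loss with respect to the whole
model at once.  Every :class:`Module` builds its initial tree at construction
time from an explicit ``numpy.random.Generator`` and reads the (possibly
autograd-boxed) tree passed to ``forward``.  Mutable, non-differentiable state
(batch-norm running statistics) stays on the module object and is updated with
unboxed values during training forwards.

Convolutions are im2col gathers followed by ``einsum``; all index arrays are
plain (untraced) numpy, so only the dense linear algebra enters the autograd
tape.
"""

from __future__ import annotations

import math

import autograd.numpy as anp
import numpy as np
from autograd.tracer import getval

F32 = np.float32


# ---------------------------------------------------------------------------
# functional ops
# ---------------------------------------------------------------------------

def relu(x):
    return anp.maximum(x, 0.0)


def gelu(x):
    # tanh approximation, adequate at float32 for gating/MLP use; the clip
    # is inside the tanh saturation region and avoids cosh overflow in vjps
    c = math.sqrt(2.0 / math.pi)
    return 0.5 * x * (1.0 + anp.tanh(anp.clip(c * (x + 0.044715 * x**3), -20.0, 20.0)))


def sigmoid(x):
    # tanh form avoids exp overflow at large |x|
    return 0.5 * (1.0 + anp.tanh(anp.clip(0.5 * x, -20.0, 20.0)))


def hardswish(x):
    return x * anp.clip(x + 3.0, 0.0, 6.0) / 6.0


def softmax(x, axis=-1):
    z = x - anp.max(x, axis=axis, keepdims=True)
    e = anp.exp(z)
    return e / anp.sum(e, axis=axis, keepdims=True)


def _im2col_indices(h, w, kh, kw, stride, pad):
    oh = (h + 2 * pad - kh) // stride + 1
    ow = (w + 2 * pad - kw) // stride + 1
    i0 = np.repeat(np.arange(kh), kw)
    j0 = np.tile(np.arange(kw), kh)
    i1 = stride * np.repeat(np.arange(oh), ow)
    j1 = stride * np.tile(np.arange(ow), oh)
    ii = i0[:, None] + i1[None, :]          # (kh*kw, oh*ow)
    jj = j0[:, None] + j1[None, :]
    return ii, jj, oh, ow


def conv2d(x, w, b=None, stride=1, pad=0):
    """2D convolution. x (B,C,H,W), w (O,C,kh,kw), b (O,) or None."""
    B = x.shape[0]
    C, H, W = x.shape[1], x.shape[2], x.shape[3]
    O, _, kh, kw = w.shape
    if pad > 0:
        x = anp.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="constant")
    ii, jj, oh, ow = _im2col_indices(H, W, kh, kw, stride, pad)
    patches = x[:, :, ii, jj]                      # (B, C, kh*kw, oh*ow)
    patches = anp.reshape(patches, (B, C * kh * kw, oh * ow))
    wmat = anp.reshape(w, (O, C * kh * kw))
    out = anp.matmul(wmat, patches)                # (O,P) @ (B,P,L) -> (B,O,L)
    if b is not None:
        out = out + anp.reshape(b, (1, O, 1))
    return anp.reshape(out, (B, O, oh, ow))


def depthwise_conv2d(x, w, b=None, stride=1, pad=0):
    """Depth-wise 2D convolution. w (C,kh,kw)."""
    B = x.shape[0]
    C, H, W = x.shape[1], x.shape[2], x.shape[3]
    kh, kw = w.shape[1], w.shape[2]
    if pad > 0:
        x = anp.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)), mode="constant")
    ii, jj, oh, ow = _im2col_indices(H, W, kh, kw, stride, pad)
    patches = x[:, :, ii, jj]                      # (B, C, kh*kw, oh*ow)
    wmat = anp.reshape(w, (C, kh * kw))
    out = anp.einsum("ck,bckl->bcl", wmat, patches)
    if b is not None:
        out = out + anp.reshape(b, (1, C, 1))
    return anp.reshape(out, (B, C, oh, ow))


def linear(x, w, b=None):
    """Affine map along the last axis. w (in, out)."""
    out = anp.matmul(x, w)
    if b is not None:
        out = out + b
    return out


def layer_norm(x, gamma, beta, eps=1e-5):
    mu = anp.mean(x, axis=-1, keepdims=True)
    var = anp.mean((x - mu) ** 2, axis=-1, keepdims=True)
    return gamma * (x - mu) / anp.sqrt(var + eps) + beta


def global_avg_pool(x):
    """(B,C,H,W) -> (B,C)."""
    return anp.mean(x, axis=(2, 3))


def bilinear_resize(x, out_h, out_w):
    """Differentiable bilinear resize of (B,C,H,W), align_corners=False."""
    H, W = x.shape[2], x.shape[3]
    if H == out_h and W == out_w:
        return x
    ys = (np.arange(out_h) + 0.5) * (H / out_h) - 0.5
    xs = (np.arange(out_w) + 0.5) * (W / out_w) - 0.5
    ys = np.clip(ys, 0, H - 1)
    xs = np.clip(xs, 0, W - 1)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, H - 1)
    x1 = np.minimum(x0 + 1, W - 1)
    wy = (ys - y0).astype(F32)[:, None]            # (out_h, 1)
    wx = (xs - x0).astype(F32)[None, :]            # (1, out_w)
    p00 = x[:, :, y0[:, None], x0[None, :]]
    p01 = x[:, :, y0[:, None], x1[None, :]]
    p10 = x[:, :, y1[:, None], x0[None, :]]
    p11 = x[:, :, y1[:, None], x1[None, :]]
    top = p00 * (1 - wx) + p01 * wx
    bot = p10 * (1 - wx) + p11 * wx
    return top * (1 - wy) + bot * wy


def to_tokens(x):
    """(B,C,H,W) -> (B, H*W, C)."""
    B, C, H, W = x.shape
    return anp.reshape(anp.transpose(x, (0, 2, 3, 1)), (B, H * W, C))


def to_map(t, h, w):
    """(B, H*W, C) -> (B,C,H,W)."""
    B, N, C = t.shape
    return anp.transpose(anp.reshape(t, (B, h, w, C)), (0, 3, 1, 2))


# ---------------------------------------------------------------------------
# initializers
# ---------------------------------------------------------------------------

def he_conv(rng, o, c, kh, kw):
    std = math.sqrt(2.0 / (c * kh * kw))
    return (rng.standard_normal((o, c, kh, kw)) * std).astype(F32)


def xavier_linear(rng, fan_in, fan_out):
    std = math.sqrt(2.0 / (fan_in + fan_out))
    return (rng.standard_normal((fan_in, fan_out)) * std).astype(F32)


def zeros(*shape):
    return np.zeros(shape, dtype=F32)


def ones(*shape):
    return np.ones(shape, dtype=F32)


# ---------------------------------------------------------------------------
# module system
# ---------------------------------------------------------------------------

class Module:
    """Base class: explicit param registry + child registry.

    ``forward(p, x, ...)`` receives this module's own subtree ``p`` (a dict
    whose leaves may be autograd boxes during a backward pass).
    """

    def __init__(self):
        self._params: dict[str, np.ndarray] = {}
        self._mods: dict[str, "Module"] = {}
        self.training = False

    def add_param(self, name, arr):
        self._params[name] = arr
        return arr

    def add_module(self, name, mod):
        self._mods[name] = mod
        return mod

    def param_tree(self):
        tree = {k: v for k, v in self._params.items()}
        for k, m in self._mods.items():
            tree[k] = m.param_tree()
        return tree

    def set_training(self, flag: bool):
        self.training = flag
        for m in self._mods.values():
            m.set_training(flag)
        return self

    def state_dict(self):
        """Mutable (non-differentiable) state, keyed like the param tree."""
        out = {}
        for k, m in self._mods.items():
            sub = m.state_dict()
            if sub:
                out[k] = sub
        local = self._local_state()
        if local:
            out.update(local)
        return out

    def load_state(self, state):
        for k, m in self._mods.items():
            if k in state:
                m.load_state(state[k])
        self._load_local_state(state)

    def _local_state(self):
        return {}

    def _load_local_state(self, state):
        pass

    def forward(self, p, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


def tree_flatten(tree, prefix=""):
    """Deterministic (sorted) flattening of a param tree to path->leaf."""
    out = {}
    for k in sorted(tree):
        v = tree[k]
        path = f"{prefix}{k}" if not prefix else f"{prefix}/{k}"
        if isinstance(v, dict):
            out.update(tree_flatten(v, path))
        else:
            out[path] = v
    return out


def tree_unflatten(flat):
    tree: dict = {}
    for path, leaf in flat.items():
        parts = path.split("/")
        node = tree
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = leaf
    return tree


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Conv2d(Module):
    def __init__(self, rng, c_in, c_out, k=3, stride=1, pad=None, bias=True):
        super().__init__()
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad
        self.add_param("w", he_conv(rng, c_out, c_in, k, k))
        if bias:
            self.add_param("b", zeros(c_out))

    def forward(self, p, x):
        return conv2d(x, p["w"], p.get("b"), stride=self.stride, pad=self.pad)


class DWConv2d(Module):
    def __init__(self, rng, c, k=3, bias=True):
        super().__init__()
        self.pad = k // 2
        std = math.sqrt(2.0 / (k * k))
        self.add_param("w", (rng.standard_normal((c, k, k)) * std).astype(F32))
        if bias:
            self.add_param("b", zeros(c))

    def forward(self, p, x):
        return depthwise_conv2d(x, p["w"], p.get("b"), stride=1, pad=self.pad)


class Linear(Module):
    def __init__(self, rng, f_in, f_out, bias=True):
        super().__init__()
        self.add_param("w", xavier_linear(rng, f_in, f_out))
        if bias:
            self.add_param("b", zeros(f_out))

    def forward(self, p, x):
        return linear(x, p["w"], p.get("b"))


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.add_param("gamma", ones(c))
        self.add_param("beta", zeros(c))
        self.running_mean = zeros(c)
        self.running_var = ones(c)

    def forward(self, p, x):
        g = anp.reshape(p["gamma"], (1, -1, 1, 1))
        b = anp.reshape(p["beta"], (1, -1, 1, 1))
        if self.training:
            mu = anp.mean(x, axis=(0, 2, 3))
            var = anp.mean((x - anp.reshape(mu, (1, -1, 1, 1))) ** 2, axis=(0, 2, 3))
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * getval(mu)).astype(F32)
            self.running_var = ((1 - m) * self.running_var + m * getval(var)).astype(F32)
        else:
            mu, var = self.running_mean, self.running_var
        mu = anp.reshape(mu, (1, -1, 1, 1))
        var = anp.reshape(var, (1, -1, 1, 1))
        return g * (x - mu) / anp.sqrt(var + self.eps) + b

    def _local_state(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def _load_local_state(self, state):
        if "running_mean" in state:
            self.running_mean = np.asarray(state["running_mean"], dtype=F32)
            self.running_var = np.asarray(state["running_var"], dtype=F32)


class LayerNorm(Module):
    def __init__(self, d, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.add_param("gamma", ones(d))
        self.add_param("beta", zeros(d))

    def forward(self, p, x):
        return layer_norm(x, p["gamma"], p["beta"], self.eps)


class ConvBNAct(Module):
    """conv -> BN -> activation, the basic CNN building block."""

    def __init__(self, rng, c_in, c_out, k=3, stride=1, act=relu):
        super().__init__()
        self.act = act
        self.add_module("conv", Conv2d(rng, c_in, c_out, k=k, stride=stride, bias=False))
        self.add_module("bn", BatchNorm2d(c_out))

    def forward(self, p, x):
        x = self._mods["conv"].forward(p["conv"], x)
        x = self._mods["bn"].forward(p["bn"], x)
        return self.act(x)
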