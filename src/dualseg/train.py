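"""Training, prediction and checkpointing.

Optimization follows the published protocol: Adam, initial learning rate
3e-4, weight decay 1e-4, batch size 16 (constant learning rate).  The loss
is an even blend of pixel cross-entropy and soft Dice over foreground
classes.  Every checkpoint and history file embeds the fully resolved run
configuration and seed; runs with the same seed are bit-reproducible.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import autograd.numpy as anp
import numpy as np
from autograd import value_and_grad
from autograd.scipy.special import logsumexp

from . import metrics as seg_metrics
from .config import RunConfig, config_to_dict
from .model import DualBranchSegNet, build_model
from .nn import tree_flatten, tree_unflatten
from .synthetic import load_manifest, load_pair


# ---------------------------------------------------------------------------
# loss
# ---------------------------------------------------------------------------

def segmentation_loss(logits, targets, num_classes, ce_weight=0.5, dice_weight=0.5):
    """ce_weight * cross-entropy + dice_weight * (1 - soft foreground Dice)."""
    onehot = np.eye(num_classes, dtype=np.float32)[targets]          # (B,H,W,L)
    onehot = np.transpose(onehot, (0, 3, 1, 2))
    logz = logsumexp(logits, axis=1, keepdims=True)
    logp = logits - logz
    ce = -anp.mean(anp.sum(onehot * logp, axis=1))
    probs = anp.exp(logp)
    eps = 1e-6
    inter = anp.sum(probs * onehot, axis=(0, 2, 3))
    sizes = anp.sum(probs, axis=(0, 2, 3)) + anp.sum(onehot, axis=(0, 2, 3))
    soft_dice = (2.0 * inter + eps) / (sizes + eps)
    dice_loss = 1.0 - anp.mean(soft_dice[1:])                        # foreground classes
    return ce_weight * ce + dice_weight * dice_loss


# ---------------------------------------------------------------------------
# Adam
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, flat_params, lr=3e-4, weight_decay=1e-4,
                 beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in flat_params.items()}
        self.v = {k: np.zeros_like(v) for k, v in flat_params.items()}

    def step(self, flat_params, flat_grads):
        self.t += 1
        out = {}
        for k, p in flat_params.items():
            g = flat_grads[k].astype(np.float32)
            if self.wd and p.ndim >= 2:
                g = g + self.wd * p
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            out[k] = (p - self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
        return out


# ---------------------------------------------------------------------------
# checkpoint I/O
# ---------------------------------------------------------------------------

def save_checkpoint(path, model, params, run_cfg: RunConfig, extra=None,
                    optimizer=None, rng=None):
    flat_p = tree_flatten(params)
    flat_s = tree_flatten(model.state_dict()) if model.state_dict() else {}
    blob = {f"param:{k}": v for k, v in flat_p.items()}
    blob.update({f"state:{k}": v for k, v in flat_s.items()})
    meta = {"run_config": config_to_dict(run_cfg), "extra": extra or {}}
    if optimizer is not None:
        blob.update({f"adam_m:{k}": v for k, v in optimizer.m.items()})
        blob.update({f"adam_v:{k}": v for k, v in optimizer.v.items()})
        meta["adam_t"] = optimizer.t
    if rng is not None:
        state = rng.bit_generator.state
        meta["rng_state"] = {"bit_generator": state["bit_generator"],
                             "state": {k: int(v) if isinstance(v, (int, np.integer)) else v
                                       for k, v in state["state"].items()},
                             "has_uint32": int(state.get("has_uint32", 0)),
                             "uinteger": int(state.get("uinteger", 0))}
    blob["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    np.savez(path, **blob)


def load_checkpoint(path):
    """Returns (model, params, run_cfg, extra); model is in eval mode."""
    with np.load(path) as z:
        meta = json.loads(bytes(z["meta_json"]).decode())
        flat_p = {k[len("param:"):]: z[k] for k in z.files if k.startswith("param:")}
        flat_s = {k[len("state:"):]: z[k] for k in z.files if k.startswith("state:")}
    from .config import run_config_from_dict
    run_cfg = run_config_from_dict(meta["run_config"])
    model = DualBranchSegNet(run_cfg.model)
    params = tree_unflatten(flat_p)
    if flat_s:
        model.load_state(tree_unflatten(flat_s))
    model.set_training(False)
    return model, params, run_cfg, meta.get("extra", {})


# ---------------------------------------------------------------------------
# data helpers
# ---------------------------------------------------------------------------

def load_split(data_dir):
    man = load_manifest(data_dir)
    out = {}
    for split in ("train", "val"):
        imgs, masks = [], []
        for name in man[split]:
            im, mk = load_pair(data_dir, name)
            imgs.append(im)
            masks.append(mk)
        out[split] = (np.stack(imgs).astype(np.float32), np.stack(masks))
    return out, man


def predict_batch(model, params, images, batch_size=16):
    """Argmax label maps for a stack of images, eval mode, batch-invariant."""
    model.set_training(False)
    outs = []
    for i in range(0, len(images), batch_size):
        logits = model.forward(params, images[i:i + batch_size])
        outs.append(np.argmax(logits, axis=1).astype(np.uint8))
    return np.concatenate(outs, axis=0)


def validation_dice(model, params, images, masks, num_classes, batch_size=16):
    """Mean over images of the macro foreground Dice."""
    preds = predict_batch(model, params, images, batch_size)
    vals = []
    for pr, gt in zip(preds, masks):
        rep = seg_metrics.evaluate(gt, pr, num_classes)
        vals.append(rep.macro["dice"])
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

def train(run_cfg: RunConfig, progress: bool = False, resume: bool = False):
    """Seeded end-to-end training from a fixture directory.

    Writes ``history.jsonl`` (one record per epoch), the best-validation
    checkpoint ``best.npz`` and a resumable ``last.npz`` to
    ``run_cfg.out_dir``.  With ``resume=True`` an existing ``last.npz``
    continues the run bit-exactly (parameters, Adam moments, shuffling RNG
    state and history are all restored).  Returns a summary dict.
    """
    if run_cfg.data_dir is None or run_cfg.out_dir is None:
        raise ValueError("run_cfg.data_dir and run_cfg.out_dir are required")
    out_dir = Path(run_cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data, _ = load_split(run_cfg.data_dir)
    x_train, y_train = data["train"]
    x_val, y_val = data["val"]
    L = run_cfg.model.num_classes

    model, params = build_model(run_cfg.model)
    flat = tree_flatten(params)
    opt = Adam(flat, lr=run_cfg.optimizer.lr, weight_decay=run_cfg.optimizer.weight_decay)
    rng = np.random.default_rng(run_cfg.seed)
    start_epoch = 0
    prev_records: list[dict] = []
    last_path = out_dir / "last.npz"
    if resume and last_path.exists():
        with np.load(last_path) as z:
            meta = json.loads(bytes(z["meta_json"]).decode())
            flat = {k[len("param:"):]: z[k] for k in z.files if k.startswith("param:")}
            flat_s = {k[len("state:"):]: z[k] for k in z.files if k.startswith("state:")}
            opt.m = {k[len("adam_m:"):]: z[k] for k in z.files if k.startswith("adam_m:")}
            opt.v = {k[len("adam_v:"):]: z[k] for k in z.files if k.startswith("adam_v:")}
        opt.t = meta["adam_t"]
        if flat_s:
            model.load_state(tree_unflatten(flat_s))
        rng.bit_generator.state = meta["rng_state"]
        start_epoch = meta["extra"]["epoch"] + 1
        hist_file = out_dir / "history.jsonl"
        if hist_file.exists():
            prev_records = [json.loads(ln) for ln in
                            hist_file.read_text().strip().splitlines() if ln]

    def batch_loss(p, xb, yb):
        logits = model.forward(p, xb)
        return segmentation_loss(logits, yb, L, run_cfg.ce_weight, run_cfg.dice_weight)

    loss_and_grad = value_and_grad(batch_loss)
    history_path = out_dir / "history.jsonl"
    if start_epoch == 0:
        history_path.write_text("")
    best_dice = max((r["val_macro_dice"] for r in prev_records), default=-1.0)
    n = len(x_train)
    bs = run_cfg.batch_size
    records = list(prev_records)

    for epoch in range(start_epoch, run_cfg.epochs):
        model.set_training(True)
        order = rng.permutation(n)
        losses = []
        t0 = time.time()
        for i in range(0, n, bs):
            idx = order[i:i + bs]
            params = tree_unflatten(flat)
            val, grads = loss_and_grad(params, x_train[idx], y_train[idx])
            if not np.isfinite(val):
                raise RuntimeError(
                    f"non-finite loss {val} at epoch {epoch}, step {i // bs}")
            flat = opt.step(flat, tree_flatten(grads))
            losses.append(float(val))
        params = tree_unflatten(flat)
        vdice = validation_dice(model, params, x_val, y_val, L, bs)
        rec = {"epoch": epoch, "train_loss": float(np.mean(losses)),
               "val_macro_dice": vdice}
        records.append(rec)
        with history_path.open("a") as fh:
            fh.write(json.dumps(rec) + "\n")
        if progress:
            print(f"epoch {epoch}: loss {rec['train_loss']:.4f} "
                  f"val dice {vdice:.4f} ({time.time() - t0:.1f}s)")
        if vdice > best_dice:
            best_dice = vdice
            save_checkpoint(out_dir / "best.npz", model, params, run_cfg,
                            extra={"epoch": epoch, "val_macro_dice": vdice})
        save_checkpoint(last_path, model, params, run_cfg,
                        extra={"epoch": epoch, "val_macro_dice": vdice},
                        optimizer=opt, rng=rng)
        if run_cfg.early_stop_dice is not None and vdice >= run_cfg.early_stop_dice:
            break

    summary = {"best_val_macro_dice": best_dice, "epochs_run": len(records),
               "history": records}
    (out_dir / "summary.json").write_text(json.dumps(
        {k: v for k, v in summary.items() if k != "history"}, indent=2))
    return summary
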