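"""Segmentation evaluation: Dice, IoU, signed relative volume difference,
and the average / maximum symmetric surface (boundary) distances.

Overlap metrics are exact integer-ratio computations.  Surface metrics
extract 4-connectivity boundary pixels and measure Euclidean nearest-boundary
distances through an exact distance transform, with optional anisotropic
pixel spacing.  Empty-mask conventions: both masks empty gives Dice = IoU = 1;
a metric that needs a nonempty mask returns NaN (with a warning) and the
class is excluded from macro averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

_CROSS = ndimage.generate_binary_structure(2, 1)   # 4-connectivity

METRIC_NAMES = ("dice", "iou", "ravd", "assd", "mssd")


def _check_pair(gt, seg):
    gt = np.asarray(gt).astype(bool)
    seg = np.asarray(seg).astype(bool)
    if gt.shape != seg.shape:
        raise ValueError(f"mask shape mismatch: {gt.shape} vs {seg.shape}")
    return gt, seg


def dice(gt, seg) -> float:
    """2|gt & seg| / (|gt| + |seg|); 1.0 when both masks are empty."""
    gt, seg = _check_pair(gt, seg)
    denom = int(gt.sum()) + int(seg.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((gt & seg).sum()) / denom


def iou(gt, seg) -> float:
    """|gt & seg| / |gt | seg|; 1.0 when both masks are empty."""
    gt, seg = _check_pair(gt, seg)
    union = int((gt | seg).sum())
    if union == 0:
        return 1.0
    return int((gt & seg).sum()) / union


def ravd(gt, seg) -> float:
    """Signed relative volume difference |seg|/|gt| - 1; NaN for empty gt."""
    gt, seg = _check_pair(gt, seg)
    n_gt = int(gt.sum())
    if n_gt == 0:
        warnings.warn("ravd undefined for empty ground-truth mask; returning NaN")
        return float("nan")
    return int(seg.sum()) / n_gt - 1.0


def boundary(mask) -> np.ndarray:
    """Pixels of the mask with at least one 4-neighbor outside it."""
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros_like(mask)
    inner = ndimage.binary_erosion(mask, structure=_CROSS, border_value=0)
    return mask & ~inner


def _surface_distances(gt, seg, spacing):
    """Directed nearest-boundary distances (seg->gt, gt->seg)."""
    bg = boundary(gt)
    bs = boundary(seg)
    dt_gt = ndimage.distance_transform_edt(~bg, sampling=spacing)
    dt_seg = ndimage.distance_transform_edt(~bs, sampling=spacing)
    return dt_gt[bs], dt_seg[bg]


def assd(gt, seg, spacing=(1.0, 1.0)) -> float:
    """Average symmetric surface distance over both boundary point sets."""
    gt, seg = _check_pair(gt, seg)
    if not gt.any() or not seg.any():
        warnings.warn("assd undefined for an empty mask; returning NaN")
        return float("nan")
    d_sg, d_gs = _surface_distances(gt, seg, spacing)
    return float((d_sg.sum() + d_gs.sum()) / (d_sg.size + d_gs.size))


def mssd(gt, seg, spacing=(1.0, 1.0)) -> float:
    """Maximum symmetric surface distance (boundary Hausdorff distance)."""
    gt, seg = _check_pair(gt, seg)
    if not gt.any() or not seg.any():
        warnings.warn("mssd undefined for an empty mask; returning NaN")
        return float("nan")
    d_sg, d_gs = _surface_distances(gt, seg, spacing)
    return float(max(d_sg.max(), d_gs.max()))


@dataclass
class MetricReport:
    """Per-class and macro metric values; macro averages skip NaN classes."""

    per_class: dict[int, dict[str, float]] = field(default_factory=dict)
    macro: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"per_class": {str(k): v for k, v in self.per_class.items()},
                "macro": dict(self.macro)}


def evaluate(gt, seg, num_classes: int, spacing=(1.0, 1.0)) -> MetricReport:
    """Score every foreground class (1..L-1) of a label-image pair.

    Classes absent from both masks are skipped entirely; metrics that are
    undefined for a class (empty on one side) contribute NaN to that class
    and are excluded from the macro mean.
    """
    gt = np.asarray(gt)
    seg = np.asarray(seg)
    if gt.shape != seg.shape:
        raise ValueError(f"mask shape mismatch: {gt.shape} vs {seg.shape}")
    for arr, name in ((gt, "gt"), (seg, "seg")):
        if arr.min() < 0 or arr.max() >= num_classes:
            raise ValueError(f"{name} labels outside [0, {num_classes})")
    report = MetricReport()
    for cls in range(1, num_classes):
        g = gt == cls
        s = seg == cls
        if not g.any() and not s.any():
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report.per_class[cls] = {
                "dice": dice(g, s),
                "iou": iou(g, s),
                "ravd": ravd(g, s),
                "assd": assd(g, s, spacing),
                "mssd": mssd(g, s, spacing),
            }
    for name in METRIC_NAMES:
        vals = [v[name] for v in report.per_class.values() if np.isfinite(v[name])]
        report.macro[name] = float(np.mean(vals)) if vals else float("nan")
    return report
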