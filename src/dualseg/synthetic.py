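"""Seeded synthetic shape-segmentation fixtures.

The generator emulates the structure that makes clinical segmentation hard:
one large organ-like elliptical structure per image, small low-contrast
lesion-like targets (radius capped at 6 px), optionally a second organ class
touching the first (shared boundary), Gaussian-blurred contours and additive
Gaussian intensity noise.  The label mask is the pre-blur geometry, so
boundary blur creates genuinely ambiguous contours in the image.

Everything is a pure function of (spec.seed, index): per-index seed
sequences make sample ``i`` identical whether generated alone or in a run.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage


@dataclass
class ObjectMeta:
    cls: int
    center: tuple[float, float]
    radius: float          # semi-major axis, px


@dataclass
class FixtureSpec:
    n_images: int = 250
    size: int = 64
    num_classes: int = 3
    organ_radius: tuple[float, float] = (10.0, 20.0)
    lesion_radius: tuple[float, float] = (4.0, 6.0)
    lesions_per_image: tuple[int, int] = (1, 2)
    touching_pair: bool = False        # second organ class touching the first
    boundary_blur_sigma: float = 0.7   # px
    noise_sigma: float = 0.03
    contrast_jitter: float = 0.05      # per-object intensity jitter half-range
    intensities: tuple[float, ...] = (0.15, 0.55, 0.9, 0.4)  # per class
    fg_frac_bounds: tuple[float, float] = (0.01, 0.6)
    train_frac: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if self.size % 16:
            raise ValueError("size must be divisible by 16")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.lesion_radius[1] > 6.0:
            raise ValueError("lesion radius is capped at 6 px")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FixtureSpec":
        kwargs = {f.name: d[f.name] for f in dataclasses.fields(cls) if f.name in d}
        for k, v in kwargs.items():
            if isinstance(v, list):
                kwargs[k] = tuple(v)
        return cls(**kwargs)


EASY = FixtureSpec()
HARD = FixtureSpec(
    num_classes=4,
    touching_pair=True,
    lesion_radius=(3.0, 6.0),
    boundary_blur_sigma=1.5,
    noise_sigma=0.08,
    intensities=(0.15, 0.55, 0.65, 0.45),
    contrast_jitter=0.08,
)

PRESETS = {"easy": EASY, "hard": HARD}


@dataclass
class SyntheticSample:
    image: np.ndarray            # float32 (1, size, size) in [0, 1]
    mask: np.ndarray             # uint8 (size, size), labels 0..L-1
    metadata: list[ObjectMeta] = field(default_factory=list)


def _ellipse_mask(size, cy, cx, ry, rx, theta):
    yy, xx = np.mgrid[0:size, 0:size]
    y = yy - cy
    x = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (x * ct + y * st) / rx
    v = (-x * st + y * ct) / ry
    return u * u + v * v <= 1.0


def _sample_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def generate_sample(spec: FixtureSpec, index: int) -> SyntheticSample:
    """Render sample ``index``; deterministic in (spec.seed, index)."""
    rng = _sample_rng(spec.seed, index)
    size = spec.size
    labels = np.zeros((size, size), dtype=np.uint8)
    meta: list[ObjectMeta] = []

    # large organ (class 1); radii clipped so the ellipse fits small canvases
    r_hi = min(spec.organ_radius[1], 0.3 * size)
    r_lo = min(spec.organ_radius[0], 0.6 * r_hi)
    ry = rng.uniform(r_lo, r_hi)
    rx = rng.uniform(0.6 * ry, ry)
    margin = ry + 2
    cy = rng.uniform(margin, size - margin)
    cx = rng.uniform(margin, size - margin)
    theta = rng.uniform(0, np.pi)
    organ = _ellipse_mask(size, cy, cx, ry, rx, theta)
    labels[organ] = 1
    meta.append(ObjectMeta(1, (cy, cx), float(ry)))

    # optional second organ class touching the first (shared boundary)
    if spec.touching_pair and spec.num_classes >= 4:
        for _ in range(50):
            ry2 = rng.uniform(r_lo * 0.6, r_hi * 0.8)
            rx2 = rng.uniform(0.6 * ry2, ry2)
            ang = rng.uniform(0, 2 * np.pi)
            dist = 0.95 * (min(ry, rx) + min(ry2, rx2))
            cy2 = cy + dist * np.sin(ang)
            cx2 = cx + dist * np.cos(ang)
            if ry2 < cy2 < size - ry2 and ry2 < cx2 < size - ry2:
                second = _ellipse_mask(size, cy2, cx2, ry2, rx2, rng.uniform(0, np.pi))
                if (second & organ).sum() == 0:
                    continue    # require an actual shared boundary
                labels[second & (labels == 0)] = 3
                meta.append(ObjectMeta(3, (cy2, cx2), float(ry2)))
                break
        else:
            raise RuntimeError(f"could not place a touching organ pair in sample {index}")

    # small lesions (class 2), preferentially inside the organ
    n_lo, n_hi = spec.lesions_per_image
    n_lesions = int(rng.integers(n_lo, n_hi + 1))
    for _ in range(n_lesions):
        placed = False
        for _try in range(100):
            rl = rng.uniform(*spec.lesion_radius)
            ly = rng.uniform(rl + 1, size - rl - 1)
            lx = rng.uniform(rl + 1, size - rl - 1)
            # minor axis kept below 0.95*rl so the pixelated area stays
            # under the pi * 6^2 small-target budget
            lesion = _ellipse_mask(size, ly, lx, rl, rng.uniform(0.7 * rl, 0.95 * rl),
                                   rng.uniform(0, np.pi))
            # lesions must not touch each other (each component stays small)
            if (ndimage.binary_dilation(lesion) & (labels == 2)).any():
                continue
            # keep lesions inside the organ when possible
            if organ[int(round(ly)), int(round(lx))] or _try > 60:
                labels[lesion] = 2
                meta.append(ObjectMeta(2, (ly, lx), float(rl)))
                placed = True
                break
        if not placed:
            raise RuntimeError(f"could not place a lesion in sample {index}")

    # render intensities with per-object jitter, blur, then add noise
    base = np.asarray(spec.intensities, dtype=np.float64)
    img = np.full((size, size), base[0], dtype=np.float64)
    for cls in range(1, spec.num_classes):
        sel = labels == cls
        if sel.any():
            jitter = rng.uniform(-spec.contrast_jitter, spec.contrast_jitter)
            img[sel] = base[cls % len(base)] + jitter
    if spec.boundary_blur_sigma > 0:
        img = ndimage.gaussian_filter(img, spec.boundary_blur_sigma)
    if spec.noise_sigma > 0:
        img = img + rng.normal(0, spec.noise_sigma, img.shape)
    img = np.clip(img, 0.0, 1.0).astype(np.float32)
    return SyntheticSample(img[None], labels, meta)


def generate_dataset(spec: FixtureSpec) -> list[SyntheticSample]:
    return [generate_sample(spec, i) for i in range(spec.n_images)]


def write_dataset(spec: FixtureSpec, out_dir) -> dict:
    """Write images/ and masks/ PNG pairs plus a JSON manifest.

    Images are 8-bit grayscale PNGs; masks are 8-bit label-index PNGs
    (lossless round trip).  Returns the manifest dict.
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    names = []
    for i in range(spec.n_images):
        s = generate_sample(spec, i)
        name = f"sample_{i:04d}.png"
        img8 = np.round(s.image[0] * 255).astype(np.uint8)
        Image.fromarray(img8, mode="L").save(out / "images" / name)
        Image.fromarray(s.mask, mode="L").save(out / "masks" / name)
        names.append(name)
    n_train = int(round(spec.train_frac * spec.n_images))
    manifest = {
        "spec": spec.to_dict(),
        "train": names[:n_train],
        "val": names[n_train:],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_pair(data_dir, name):
    """Load one (image, mask) PNG pair back to float32 / uint8 arrays."""
    data_dir = Path(data_dir)
    img = np.asarray(Image.open(data_dir / "images" / name), dtype=np.float32) / 255.0
    mask = np.asarray(Image.open(data_dir / "masks" / name), dtype=np.uint8)
    return img[None], mask


def load_manifest(data_dir) -> dict:
    return json.loads((Path(data_dir) / "manifest.json").read_text())
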