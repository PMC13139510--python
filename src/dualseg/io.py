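"""Image and mask I/O: 8-bit PNG pairs and optional NIfTI volumes.

NIfTI volumes are reoriented to RAS canonical orientation before axial
(last-axis) slices are extracted, so slice order and in-plane orientation
are consistent across differently stored volumes.  Label slices round-trip
losslessly through the same path.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image


def read_image(path) -> np.ndarray:
    """Read a grayscale or RGB image to float32 (C, H, W) in [0, 1]."""
    arr = np.asarray(Image.open(path))
    if arr.ndim == 2:
        arr = arr[None]
    else:
        arr = np.transpose(arr[..., :3], (2, 0, 1))
    return arr.astype(np.float32) / 255.0


def read_mask(path) -> np.ndarray:
    """Read an 8-bit label-index mask PNG."""
    return np.asarray(Image.open(path), dtype=np.uint8)


def write_mask(path, mask: np.ndarray) -> None:
    Image.fromarray(np.asarray(mask, dtype=np.uint8), mode="L").save(path)


def is_nifti(path) -> bool:
    name = str(path)
    return name.endswith(".nii") or name.endswith(".nii.gz")


def nifti_axial_slices(path, normalize: bool = True) -> list[np.ndarray]:
    """Extract axial slices from a NIfTI volume as (1, H, W) float32 arrays.

    The volume is canonicalized to RAS; axial slices are taken along the
    third (superior-inferior) axis.  Intensities are min-max normalized to
    [0, 1] over the volume unless ``normalize`` is False (label volumes).
    """
    import nibabel as nib

    img = nib.as_closest_canonical(nib.load(str(path)))
    data = np.asanyarray(img.dataobj).astype(np.float32)
    if data.ndim != 3:
        raise ValueError(f"expected a 3D volume, got shape {data.shape}")
    if normalize:
        lo, hi = float(data.min()), float(data.max())
        if hi > lo:
            data = (data - lo) / (hi - lo)
    return [np.ascontiguousarray(data[:, :, k].T)[None] for k in range(data.shape[2])]


def nifti_mask_slices(path) -> list[np.ndarray]:
    """Axial label slices of a NIfTI segmentation, dtype uint8, lossless."""
    slices = nifti_axial_slices(path, normalize=False)
    return [np.round(s[0]).astype(np.uint8) for s in slices]


def list_pngs(directory) -> list[str]:
    return sorted(p.name for p in Path(directory).glob("*.png"))
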