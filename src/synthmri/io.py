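"""Reading and writing the pipeline's file formats.

NRRD volumes go through SimpleITK; 2D grayscale slices are PNG,
written as 16-bit with intensity x stored as round(x * 65535), masks
as 8-bit 0/255.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import SimpleITK as sitk
from PIL import Image

__all__ = [
    "read_nrrd", "write_nrrd", "read_png", "write_png16",
    "read_mask_png", "write_mask_png",
]


def read_nrrd(path) -> np.ndarray:
    """Volume as a (z, y, x) float array."""
    img = sitk.ReadImage(str(path))
    return sitk.GetArrayFromImage(img).astype(np.float64)


def write_nrrd(path, volume: np.ndarray) -> None:
    """Write a (z, y, x) array as NRRD."""
    arr = np.asarray(volume)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    sitk.WriteImage(sitk.GetImageFromArray(arr), str(path))


def write_png16(path, img: np.ndarray) -> None:
    """16-bit grayscale PNG from an image in [0, 1]."""
    img = np.asarray(img, dtype=np.float64)
    if img.min() < 0 or img.max() > 1:
        raise ValueError("image values must lie in [0, 1]")
    data = np.round(img * 65535).astype(np.uint16)
    Image.fromarray(data).save(str(path))


def read_png(path) -> np.ndarray:
    """Grayscale PNG (8- or 16-bit) as a float image in [0, 1]."""
    im = Image.open(str(path))
    arr = np.asarray(im)
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    return arr.astype(np.float64) / 65535.0


def write_mask_png(path, mask: np.ndarray) -> None:
    """Binary mask as an 8-bit 0/255 PNG."""
    mask = np.asarray(mask).astype(bool)
    Image.fromarray((mask * 255).astype(np.uint8), mode="L").save(str(path))


def read_mask_png(path) -> np.ndarray:
    arr = np.asarray(Image.open(str(path)).convert("L"))
    return arr > 127


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
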