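"""Preprocessing: intensity normalization, square crop + resize, and
slice-selection rules.

The conventions mirror a typical prostate-MRI preparation chain:
volumes are min-max normalized to [0, 1] as a whole (preserving
inter-slice contrast), each slice is center-cropped to its smaller
dimension and resized to a square target, and training slices are
chosen from the contoured extent of the gland.
"""

from __future__ import annotations

import warnings

import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "normalize_intensity", "crop_square_resize",
    "select_largest_prostate_slice", "middle_contour_slices",
]


def normalize_intensity(volume: np.ndarray) -> np.ndarray:
    """Min-max normalize a whole volume to [0, 1].

    The affine map is computed over the full volume, not per slice.  A
    constant volume maps to all zeros (with a warning): there is no
    contrast to preserve.
    """
    volume = np.asarray(volume, dtype=np.float64)
    if volume.size == 0:
        raise ValueError("empty volume")
    if not np.isfinite(volume).all():
        raise ValueError("volume contains non-finite values")
    vmin = volume.min()
    vmax = volume.max()
    if vmax == vmin:
        warnings.warn("constant volume: normalizing to all zeros", stacklevel=2)
        return np.zeros_like(volume)
    return (volume - vmin) / (vmax - vmin)


def crop_square_resize(img: np.ndarray, target_size: int) -> np.ndarray:
    """Center-crop to the smaller dimension, then resize to
    ``target_size`` square.

    Images (float) are resized with bilinear interpolation; binary
    masks (bool, or integer 0/1) with nearest-neighbour so they stay
    strictly binary.  Running the operation on its own output is the
    identity.
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError("expected a 2D image or mask")
    h, w = img.shape
    if min(h, w) < 2:
        raise ValueError("image too small to crop")
    if target_size < 8:
        raise ValueError("target_size must be at least 8")

    side = min(h, w)
    top = (h - side) // 2
    left = (w - side) // 2
    cropped = img[top:top + side, left:left + side]

    is_mask = cropped.dtype == bool or (
        np.issubdtype(cropped.dtype, np.integer)
        and np.isin(np.unique(cropped), (0, 1)).all())

    if side == target_size:
        return cropped.copy()
    if is_mask:
        out = _sk_resize(cropped.astype(np.float64), (target_size, target_size),
                         order=0, anti_aliasing=False, preserve_range=True)
        out = out > 0.5
        return out if cropped.dtype == bool else out.astype(cropped.dtype)
    out = _sk_resize(cropped.astype(np.float64), (target_size, target_size),
                     order=1, anti_aliasing=side > target_size,
                     preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def _contour_areas(volume) -> np.ndarray:
    contours = volume.contours if hasattr(volume, "contours") else np.asarray(volume)
    return contours.reshape(contours.shape[0], -1).sum(axis=1)


def select_largest_prostate_slice(volume) -> int:
    """Index of the slice with the largest contour (ties -> lowest z).

    Accepts a :class:`~synthmri.phantom.PhantomVolume` or a stack of
    masks.
    """
    areas = _contour_areas(volume)
    if areas.max() == 0:
        raise ValueError("all contours are empty")
    return int(np.argmax(areas))


def middle_contour_slices(volume, k: int = 3) -> list[int]:
    """The ``k`` middle slices of the contoured extent.

    Let Z be the sorted indices of slices with a non-empty contour and
    m the lower-median position of Z; returns the k consecutive members
    of Z centered on m (shifted inward at the ends of Z).
    """
    areas = _contour_areas(volume)
    z = np.flatnonzero(areas > 0)
    if len(z) < k:
        raise ValueError(f"only {len(z)} contoured slices, need {k}")
    m = (len(z) - 1) // 2                      # lower median position
    start = m - (k - 1) // 2
    start = max(0, min(start, len(z) - k))
    return [int(i) for i in z[start:start + k]]
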