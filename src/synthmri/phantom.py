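"""Synthetic prostate-slice phantoms with contour ground truth.

The phantom emulates the geometry a T2-weighted axial pelvic slice
presents to a segmentation network: a dark background, a bright body
ellipse, a mid-intensity prostate carrying a hyperintense peripheral
rim, a hyperintense bladder above the gland, and optionally a
hypointense intra-prostatic lesion (tumours appear as low signal
against normal prostatic tissue on T2W).  A smooth polynomial bias
field and additive Gaussian noise provide the nuisance structure that
makes segmentation non-trivial.  No radiological texture realism is
attempted — the downstream stages only require a contourable
bright/dark anatomy.

Also provides degenerate images (prostate-free, fragmented, blurred)
used to probe the quality gate, and a simulated blinded-rater study
that serves as the testing oracle for the study-scoring statistics.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

__all__ = [
    "PhantomParams", "PhantomGeometry", "PhantomVolume",
    "generate_phantom_slice", "generate_phantom_volume",
    "generate_degenerate_image", "simulate_raters",
    "INTENSITY",
]

# nominal tissue intensities on the [0, 1] scale
INTENSITY = {
    "background": 0.02,
    "body": 0.35,
    "prostate": 0.55,
    "rim": 0.80,        # peripheral zone, hyperintense on T2W
    "bladder": 0.85,
    "lesion_contrast_default": 0.30,
}


@dataclass(frozen=True)
class PhantomParams:
    """Knobs of the phantom generator.

    All linear dimensions are fractions of the image side so the same
    parameters describe a 128 px desk phantom and a 500 px full-size
    one.
    """

    image_size: int = 128
    prostate_radius_range: tuple[float, float] = (0.12, 0.22)
    pz_rim_thickness: float = 0.25          # fraction of prostate radius
    lesion_probability: float = 0.3
    lesion_contrast: float = INTENSITY["lesion_contrast_default"]
    noise_sd: float = 0.03
    bias_field_amplitude: float = 0.10
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.prostate_radius_range
        if not (0.0 < lo < hi < 0.5):
            raise ValueError(
                f"prostate_radius_range must satisfy 0 < low < high < 0.5, got {self.prostate_radius_range}")
        if self.image_size < 32:
            raise ValueError("image_size must be at least 32")
        if not 0.0 <= self.lesion_probability <= 1.0:
            raise ValueError("lesion_probability must lie in [0, 1]")
        if not 0.0 <= self.lesion_contrast <= INTENSITY["prostate"]:
            raise ValueError("lesion_contrast must keep lesion intensity in [0, 1]")
        if self.noise_sd < 0 or self.bias_field_amplitude < 0:
            raise ValueError("noise_sd and bias_field_amplitude must be non-negative")
        if not 0.0 < self.pz_rim_thickness < 1.0:
            raise ValueError("pz_rim_thickness must lie in (0, 1)")


@dataclass(frozen=True)
class PhantomGeometry:
    """Sampled anatomy of one phantom, in pixel units (row, col)."""

    body_center: tuple[float, float]
    body_axes: tuple[float, float]
    prostate_center: tuple[float, float]
    prostate_radius: float          # semi-axis along columns
    prostate_aspect: float          # row semi-axis = radius * aspect
    bladder_center: tuple[float, float]
    bladder_axes: tuple[float, float]
    has_lesion: bool
    lesion_center: tuple[float, float]
    lesion_radius: float


def _ellipse(shape, center, axes) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    cy, cx = center
    ay, ax = axes
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def sample_geometry(params: PhantomParams, rng: np.random.Generator,
                    radius_factor: float = 1.0,
                    force_lesion: bool | None = None) -> PhantomGeometry:
    """Draw the anatomy for one slice.  ``radius_factor`` scales the
    prostate cross-section (used by the volume generator's z profile)."""
    S = params.image_size
    lo, hi = params.prostate_radius_range
    body_c = (0.50 * S + rng.uniform(-0.01, 0.01) * S,
              0.50 * S + rng.uniform(-0.01, 0.01) * S)
    body_ax = (0.36 * S * rng.uniform(0.95, 1.05), 0.43 * S * rng.uniform(0.95, 1.05))
    r = rng.uniform(lo, hi) * S
    aspect = rng.uniform(0.85, 1.0)
    pc = (0.60 * S + rng.uniform(-0.02, 0.02) * S,
          0.50 * S + rng.uniform(-0.02, 0.02) * S)
    bl_ax = (0.09 * S * rng.uniform(0.9, 1.1), 0.12 * S * rng.uniform(0.9, 1.1))
    bl_c = (pc[0] - r * aspect - bl_ax[0] - 0.02 * S, pc[1] + rng.uniform(-0.02, 0.02) * S)
    if force_lesion is None:
        has_lesion = rng.uniform() < params.lesion_probability
    else:
        has_lesion = force_lesion
        rng.uniform()  # keep the stream aligned with the unforced path
    # lesion strictly inside the inner gland (inside the rim)
    r_inner = r * (1.0 - params.pz_rim_thickness)
    lr = 0.35 * r_inner * rng.uniform(0.7, 1.0)
    ang = rng.uniform(0, 2 * np.pi)
    rad = rng.uniform(0, max(r_inner - lr - 1.0, 0.0) * 0.8)
    lc = (pc[0] + rad * np.sin(ang) * aspect, pc[1] + rad * np.cos(ang))
    return PhantomGeometry(body_c, body_ax, pc, r * radius_factor, aspect,
                           bl_c, bl_ax, has_lesion, lc, lr * radius_factor)


def render_slice(geom: PhantomGeometry, params: PhantomParams,
                 rng: np.random.Generator,
                 with_prostate: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Paint a geometry into a (image, mask) pair.

    The mask is the filled prostate ellipse (rim included) before any
    noise or bias field is applied.
    """
    S = params.image_size
    img = np.full((S, S), INTENSITY["background"], dtype=np.float64)
    img[_ellipse((S, S), geom.body_center, geom.body_axes)] = INTENSITY["body"]
    img[_ellipse((S, S), geom.bladder_center, geom.bladder_axes)] = INTENSITY["bladder"]
    mask = np.zeros((S, S), dtype=bool)
    if with_prostate and geom.prostate_radius >= 1.5:
        axes = (geom.prostate_radius * geom.prostate_aspect, geom.prostate_radius)
        outer = _ellipse((S, S), geom.prostate_center, axes)
        inner_axes = (axes[0] * (1 - params.pz_rim_thickness),
                      axes[1] * (1 - params.pz_rim_thickness))
        inner = _ellipse((S, S), geom.prostate_center, inner_axes)
        img[outer] = INTENSITY["rim"]
        img[inner] = INTENSITY["prostate"]
        if geom.has_lesion and geom.lesion_radius >= 1.0:
            les = _ellipse((S, S), geom.lesion_center,
                           (geom.lesion_radius, geom.lesion_radius))
            img[les & inner] = INTENSITY["prostate"] - params.lesion_contrast
        mask = outer
    if params.bias_field_amplitude > 0:
        img *= 1.0 + params.bias_field_amplitude * _bias_field(S, rng)
    else:
        rng.uniform(size=3)  # keep the stream aligned
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=(S, S))
    return np.clip(img, 0.0, 1.0), mask


def _bias_field(S: int, rng: np.random.Generator) -> np.ndarray:
    """Smooth low-order polynomial surface in [-1, 1], zero-mean-ish."""
    c = rng.uniform(-1.0, 1.0, size=3)
    y, x = np.mgrid[0:S, 0:S]
    u = 2.0 * y / (S - 1) - 1.0
    v = 2.0 * x / (S - 1) - 1.0
    f = c[0] * u + c[1] * v + c[2] * u * v
    m = np.abs(f).max()
    return f / m if m > 0 else f


def generate_phantom_slice(params: PhantomParams, seed: int | None = None
                           ) -> tuple[np.ndarray, np.ndarray, bool]:
    """One phantom slice: (image in [0,1], prostate mask, tumor flag).

    Bit-identical output for identical (params, seed).
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    geom = sample_geometry(params, rng)
    img, mask = render_slice(geom, params, rng)
    return img, mask, bool(geom.has_lesion)


@dataclass
class PhantomVolume:
    """Stack of phantom slices with aligned contours along z."""

    slices: np.ndarray              # (n, S, S) float in [0,1]
    contours: np.ndarray            # (n, S, S) bool
    lesion_labels: list[bool]
    params: PhantomParams = field(repr=False, default=None)
    seed: int = 0

    def __post_init__(self):
        if self.slices.shape != self.contours.shape:
            raise ValueError("slices and contours must be aligned stacks")

    @property
    def n_slices(self) -> int:
        return self.slices.shape[0]

    def contour_areas(self) -> np.ndarray:
        return self.contours.reshape(self.n_slices, -1).sum(axis=1)


def generate_phantom_volume(params: PhantomParams, n_slices: int = 9,
                            seed: int | None = None) -> PhantomVolume:
    """Phantom volume whose prostate cross-section follows a smooth
    spherical-cap profile peaking at the middle slice; the end slices
    fall outside the gland and carry empty contours."""
    if n_slices < 3:
        raise ValueError("n_slices must be at least 3 (middle slice undefined)")
    seed = params.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    base = sample_geometry(params, rng)
    mid = (n_slices - 1) / 2.0
    slices, contours, labels = [], [], []
    for z in range(n_slices):
        rel = (z - mid) / mid          # -1 .. 1, 0 at the middle slice
        factor = float(np.sqrt(max(0.0, 1.0 - rel * rel)))
        geom = dataclasses.replace(
            base,
            prostate_radius=base.prostate_radius * factor,
            lesion_radius=base.lesion_radius * factor,
            has_lesion=base.has_lesion and factor > 0.6,
        )
        img, mask = render_slice(geom, params, rng,
                                 with_prostate=factor > 0.0)
        slices.append(img)
        contours.append(mask)
        labels.append(bool(geom.has_lesion and mask.any()))
    return PhantomVolume(np.stack(slices), np.stack(contours), labels,
                         params=params, seed=seed)


def generate_degenerate_image(kind: str, params: PhantomParams,
                              seed: int | None = None,
                              return_mask: bool = False):
    """Pathological phantoms used to probe the quality gate.

    ``no_prostate`` omits the gland entirely; ``fragmented`` replaces it
    with several small disjoint blobs, each below the gate's 4% area
    threshold; ``blurred`` heavily smooths a normal slice and collapses
    its contrast.
    """
    rng = np.random.default_rng(params.seed if seed is None else seed)
    S = params.image_size
    if kind == "no_prostate":
        geom = sample_geometry(params, rng)
        img, _ = render_slice(geom, params, rng, with_prostate=False)
        mask = np.zeros((S, S), dtype=bool)
    elif kind == "fragmented":
        geom = sample_geometry(params, rng)
        img, _ = render_slice(geom, params, rng, with_prostate=False)
        mask = np.zeros((S, S), dtype=bool)
        # well-separated blobs of radius 0.05*S on a ring around the
        # gland position: each has area pi*(0.05 S)^2 ~ 0.8% << 4%
        r = 0.05 * S
        n_blobs = int(rng.integers(3, 5))
        pc = geom.prostate_center
        for i in range(n_blobs):
            ang = 2 * np.pi * i / n_blobs + rng.uniform(0, 0.5)
            c = (pc[0] + 0.20 * S * np.sin(ang), pc[1] + 0.20 * S * np.cos(ang))
            blob = _ellipse((S, S), c, (r, r))
            img[blob] = INTENSITY["rim"]
            mask |= blob
        img = np.clip(img + rng.normal(0, params.noise_sd, (S, S)), 0, 1)
    elif kind == "blurred":
        geom = sample_geometry(params, rng)
        img, mask = render_slice(geom, params, rng)
        img = gaussian_filter(img, sigma=0.09 * S)
        img = np.clip(0.45 + 0.15 * (img - img.mean()), 0.0, 1.0)
    else:
        raise ValueError(f"unknown degenerate kind: {kind!r}")
    return (img, mask) if return_mask else img


# ---------------------------------------------------------------------
# simulated blinded-rater study
# ---------------------------------------------------------------------

def simulate_raters(truth, per_rater_accuracy, seed: int = 0,
                    groups=None, rater_ids=None) -> pd.DataFrame:
    """Simulate a blinded conventional-vs-synthetic rating study.

    Each rater answers every image independently and is correct with
    probability equal to that rater's accuracy.  ``truth`` maps image id
    to its true class ('conventional' or 'synthetic').

    Returns the long-format study table: one row per (rater, image).
    """
    if isinstance(truth, dict):
        truth = pd.Series(truth)
    truth = pd.Series(truth)
    if len(truth) == 0:
        raise ValueError("truth is empty: no images to rate")
    bad = set(truth.unique()) - {"conventional", "synthetic"}
    if bad:
        raise ValueError(f"unknown classes in truth: {bad}")
    accs = list(per_rater_accuracy)
    if any(not 0.0 <= a <= 1.0 for a in accs):
        raise ValueError("accuracies must lie in [0, 1]")
    if groups is None:
        groups = ["none"] * len(accs)
    if rater_ids is None:
        rater_ids = [f"r{i}" for i in range(len(accs))]
    rng = np.random.default_rng(seed)
    other = {"conventional": "synthetic", "synthetic": "conventional"}
    rows = []
    for rid, grp, acc in zip(rater_ids, groups, accs):
        correct = rng.uniform(size=len(truth)) < acc
        for (img_id, true_class), ok in zip(truth.items(), correct):
            rows.append((rid, grp, img_id, true_class,
                         true_class if ok else other[true_class]))
    return pd.DataFrame(rows, columns=["rater_id", "experience_group",
                                       "image_id", "true_class", "answer"])
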