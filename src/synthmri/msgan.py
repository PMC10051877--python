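"""Single-image multi-scale GAN.

One generator/critic pair is trained per scale of a coarse-to-fine
pyramid built from a single training image.  At each scale the critic
is a Wasserstein critic with a gradient penalty, and the generator adds
an alpha-weighted reconstruction loss along a fixed-noise path that
anchors the per-scale noise amplitudes: the amplitude at scale n is
``base_amp`` times the RMSE between the real image at that scale and
the upsampled reconstruction from scale n-1 (amplitude 1 at the
coarsest scale by convention).  Sampling draws fresh noise at every
scale and propagates coarse to fine.

Scale indices are 1-based from the coarsest throughout, so "the three
finest scales" of a 10-scale stack are indices 8, 9 and 10.

All arithmetic runs on the numpy autodiff engine in
:mod:`synthmri.autodiff`; images are handled internally in [-1, 1] and
exposed in [0, 1].
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import resize as _sk_resize

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

__all__ = [
    "ScaleSchedule", "GanConfig", "GeneratorStack", "SampleRequest",
    "build_scale_schedule", "train_single_image_gan", "sample",
    "generate_pool", "save_stack", "load_stack", "DESK", "FULL",
]


# ---------------------------------------------------------------------
# scale schedule
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class ScaleSchedule:
    """Pyramid sizes, coarse -> fine."""

    sizes: tuple[tuple[int, int], ...]
    ratio: float
    coarse_min_dim: int
    start_cap: int

    @property
    def n_scales(self) -> int:
        return len(self.sizes)


def build_scale_schedule(height: int, width: int, ratio: float = 0.75,
                         coarse_min_dim: int = 25,
                         start_cap: int = 250) -> ScaleSchedule:
    """Geometric size pyramid for a (height, width) training image.

    If the image is larger than ``start_cap`` in its longer dimension it
    is first scaled down so that dimension equals the cap; the number of
    scales is the smallest N with ``finest_min_dim * ratio**(N-1) <=
    coarse_min_dim`` (equivalently ``ceil(log(cmd/fmin)/log(ratio)) +
    1``), and the intermediate sizes follow the effective geometric
    ratio between the coarsest and finest sizes.  A 500x500 image under
    the defaults yields 10 scales.
    """
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    if min(height, width) < coarse_min_dim:
        raise ValueError(
            f"image {height}x{width} smaller than coarse_min_dim={coarse_min_dim}")
    cap = min(1.0, start_cap / max(height, width))
    fh = max(coarse_min_dim, int(round(height * cap)))
    fw = max(coarse_min_dim, int(round(width * cap)))
    fmin = min(fh, fw)
    if fmin <= coarse_min_dim:
        n = 1
    else:
        n = math.ceil(math.log(coarse_min_dim / fmin) / math.log(ratio)) + 1
    sizes = []
    if n == 1:
        sizes = [(fh, fw)]
    else:
        r_eff = (coarse_min_dim / fmin) ** (1.0 / (n - 1))
        for i in range(n):
            f = r_eff ** (n - 1 - i)
            sizes.append((max(2, int(round(fh * f))), max(2, int(round(fw * f)))))
    return ScaleSchedule(tuple(sizes), ratio, coarse_min_dim, start_cap)


# ---------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class GanConfig:
    """Training configuration for the multi-scale stack."""

    ratio: float = 0.75
    coarse_min_dim: int = 25
    start_cap: int = 250
    n_blocks: int = 5               # conv blocks per network
    base_channels: int = 32
    channel_double_every: int = 4   # channels double every 4 scales
    kernel: int = 3
    gp_weight: float = 0.1
    alpha: float = 10.0             # reconstruction-loss weight
    lr: float = 5e-4
    iters_per_scale: int = 2000
    d_steps: int = 3
    g_steps: int = 3
    base_amp: float = 0.1
    seed: int = 0

    def channels(self, scale: int) -> int:
        return self.base_channels * 2 ** (scale // self.channel_double_every)


# full preset mirrors the conventional defaults of single-image GANs;
# desk preset trains a 64-128 px image on one CPU in minutes
FULL = GanConfig()
DESK = GanConfig(base_channels=16, iters_per_scale=200, d_steps=1, g_steps=1)


@dataclass(frozen=True)
class SampleRequest:
    scale_index: int                # 1-based from the coarsest
    n_samples: int = 1
    seed: int = 0
    output_size: int = 500
    reconstruction: bool = False    # use the fixed reconstruction noise


# ---------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------

class _GenNet:
    """head block + 3 body blocks + plain tail conv, tanh output."""

    def __init__(self, channels: int, n_blocks: int, k: int, rng):
        pad = k // 2
        blocks = [nn.ConvBlock(1, channels, rng, norm=False, k=k, pad=pad)]
        for _ in range(n_blocks - 2):
            blocks.append(nn.ConvBlock(channels, channels, rng, norm=True, k=k, pad=pad))
        self.body = nn.Sequential(*blocks)
        self.tail = nn.Conv2d(channels, 1, k=k, pad=pad, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.tanh(self.tail(self.body(x)))

    def params(self):
        return self.body.params() + self.tail.params()


class _CriticNet:
    """Wasserstein critic: head + body blocks + linear conv map."""

    def __init__(self, channels: int, n_blocks: int, k: int, rng):
        pad = k // 2
        blocks = [nn.ConvBlock(1, channels, rng, norm=False, k=k, pad=pad)]
        for _ in range(n_blocks - 2):
            blocks.append(nn.ConvBlock(channels, channels, rng, norm=True, k=k, pad=pad))
        self.body = nn.Sequential(*blocks)
        self.tail = nn.Conv2d(channels, 1, k=k, pad=pad, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return ad.meant(self.tail(self.body(x)))

    def params(self):
        return self.body.params() + self.tail.params()


@dataclass
class GeneratorStack:
    """Trained per-scale generators with their noise amplitudes."""

    generators: list = field(repr=False, default_factory=list)
    amplitudes: list = field(default_factory=list)      # sigma_n >= 0
    schedule: ScaleSchedule = None
    config: GanConfig = None
    z_rec: np.ndarray = field(repr=False, default=None)  # fixed scale-0 noise
    reconstructions: list = field(repr=False, default_factory=list)
    metrics: list = field(default_factory=list)  # per scale: dicts of losses

    @property
    def n_scales(self) -> int:
        return len(self.generators)


# ---------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------

def _resize01(img: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    if img.shape == tuple(size):
        return img.copy()
    out = _sk_resize(img, size, order=1, preserve_range=True,
                     anti_aliasing=img.shape[0] > size[0])
    return out


def _pyramid(img: np.ndarray, schedule: ScaleSchedule) -> list[np.ndarray]:
    """Real image at every scale, in [-1, 1], NCHW float32."""
    out = []
    for size in schedule.sizes:
        r = _resize01(img, size)
        out.append((2.0 * r - 1.0)[None, None].astype(ad.DTYPE))
    return out


def _gen_forward(gen: _GenNet, prev: Tensor, noise: Tensor) -> Tensor:
    """Residual generator step: prev + G(prev + z)."""
    return ad.add(prev, gen(ad.add(prev, noise)))


def _rmse(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.sqrt(np.mean((a - b) ** 2)))


# ---------------------------------------------------------------------
# training
# ---------------------------------------------------------------------

def train_single_image_gan(img: np.ndarray, config: GanConfig = DESK,
                           seed: int | None = None) -> GeneratorStack:
    """Train the full coarse-to-fine stack on one image in [0, 1].

    Earlier scales are frozen as later ones train.  Per scale the critic
    minimizes the Wasserstein loss with a gradient penalty and the
    generator minimizes the adversarial term plus
    ``alpha * MSE(reconstruction, real)`` along the fixed-noise path.
    Fully reproducible under a fixed seed.
    """
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2 or img.shape[0] != img.shape[1]:
        raise ValueError("training image must be 2D and square")
    if img.min() < -1e-9 or img.max() > 1 + 1e-9:
        raise ValueError("training image values must lie in [0, 1]")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)

    schedule = build_scale_schedule(img.shape[0], img.shape[1],
                                    config.ratio, config.coarse_min_dim,
                                    config.start_cap)
    reals = _pyramid(img, schedule)
    stack = GeneratorStack(schedule=schedule,
                           config=dataclasses.replace(config, seed=seed))

    for n in range(schedule.n_scales):
        _train_scale(stack, reals, n, config, rng)
    return stack


def _sample_prev(stack: GeneratorStack, upto: int, rng,
                 size: tuple[int, int]) -> np.ndarray:
    """Draw a fresh random sample through scales 0..upto-1 and upsample
    it to ``size`` (inference only, frozen scales)."""
    if upto == 0:
        return np.zeros((1, 1) + tuple(size), dtype=ad.DTYPE)
    x = None
    for k in range(upto):
        h, w = stack.schedule.sizes[k]
        prev = (np.zeros((1, 1, h, w), dtype=ad.DTYPE) if x is None
                else _upsample_nchw(x, (h, w)))
        z = (stack.amplitudes[k] *
             rng.standard_normal((1, 1, h, w))).astype(ad.DTYPE)
        x = _gen_forward(stack.generators[k], Tensor(prev), Tensor(z)).data
    return _upsample_nchw(x, size)


def _upsample_nchw(x: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    return _resize01(x[0, 0].astype(np.float64), size)[None, None].astype(ad.DTYPE)


def _train_scale(stack: GeneratorStack, reals: list[np.ndarray], n: int,
                 config: GanConfig, rng: np.random.Generator) -> None:
    real = reals[n]
    h, w = real.shape[2:]
    ch = config.channels(n)
    net_rng = np.random.default_rng(rng.integers(2**31))
    gen = _GenNet(ch, config.n_blocks, config.kernel, net_rng)
    critic = _CriticNet(ch, config.n_blocks, config.kernel, net_rng)

    # reconstruction path input and noise amplitude for this scale
    if n == 0:
        stack.z_rec = rng.standard_normal((1, 1, h, w)).astype(ad.DTYPE)
        z_rec = stack.z_rec
        prev_rec = np.zeros_like(real)
        amp = 1.0
    else:
        z_rec = np.zeros_like(real)
        prev_rec = _upsample_nchw(stack.reconstructions[n - 1],
                                  (h, w))
        amp = config.base_amp * _rmse(prev_rec, real)
    stack.amplitudes.append(float(amp))

    prev_rec_t = Tensor(prev_rec)
    z_rec_t = Tensor(z_rec)
    real_t = Tensor(real)

    rec0 = _gen_forward(gen, prev_rec_t, z_rec_t)
    mse_init = float(nn.mse(rec0, real_t).data)

    opt_g = nn.Adam(gen.params(), lr=config.lr)
    opt_c = nn.Adam(critic.params(), lr=config.lr)
    g_params, c_params = gen.params(), critic.params()

    d_losses, g_losses = [], []
    for _ in range(config.iters_per_scale):
        prev_rand = Tensor(_sample_prev(stack, n, rng, (h, w)))
        z = Tensor((amp * rng.standard_normal((1, 1, h, w))).astype(ad.DTYPE))
        fake = _gen_forward(gen, prev_rand, z)

        for _d in range(config.d_steps):
            fake_d = fake.detach()
            loss_d = ad.sub(critic(fake_d), critic(real_t))
            # gradient penalty on an interpolate between real and fake
            eps = float(rng.uniform())
            xhat = Tensor((eps * real + (1 - eps) * fake_d.data).astype(ad.DTYPE))
            (gx,) = ad.grad(critic(xhat), [xhat])
            gnorm = ad.powc(ad.add_const(ad.sumt(ad.mul(gx, gx)), 1e-12), 0.5)
            pen = ad.powc(ad.add_const(gnorm, -1.0), 2.0)
            loss_d = ad.add(loss_d, ad.cmul(pen, config.gp_weight))
            if not np.isfinite(loss_d.data):
                raise FloatingPointError(f"non-finite critic loss at scale {n}")
            opt_c.step(ad.grad(loss_d, c_params))
            d_losses.append(float(loss_d.data))

        for _g in range(config.g_steps):
            fake = _gen_forward(gen, prev_rand, z)
            rec = _gen_forward(gen, prev_rec_t, z_rec_t)
            adv = ad.neg(critic(fake))
            loss_g = ad.add(adv, ad.cmul(nn.mse(rec, real_t), config.alpha))
            if not np.isfinite(loss_g.data):
                raise FloatingPointError(f"non-finite generator loss at scale {n}")
            opt_g.step(ad.grad(loss_g, g_params))
            g_losses.append(float(loss_g.data))

    rec_final = _gen_forward(gen, prev_rec_t, z_rec_t)
    mse_final = float(nn.mse(rec_final, real_t).data)
    stack.generators.append(gen)
    stack.reconstructions.append(rec_final.data)
    stack.metrics.append({
        "scale": n, "size": (h, w), "amplitude": float(amp),
        "recon_mse_init": mse_init, "recon_mse_final": mse_final,
        "d_loss_first": d_losses[0], "d_loss_last": d_losses[-1],
        "g_loss_first": g_losses[0], "g_loss_last": g_losses[-1],
    })


# ---------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------

def sample(stack: GeneratorStack, request: SampleRequest) -> list[np.ndarray]:
    """Draw samples from the stack up to ``request.scale_index``.

    Fresh noise is drawn at every scale and propagated coarse to fine;
    with ``reconstruction=True`` the fixed-noise path is used instead
    and the result is the stored reconstruction.  Outputs are clamped to
    [0, 1] and resized to ``output_size`` square.
    """
    if not 1 <= request.scale_index <= stack.n_scales:
        raise ValueError(
            f"scale_index {request.scale_index} outside 1..{stack.n_scales}")
    rng = np.random.default_rng(request.seed)
    out = []
    for _ in range(request.n_samples):
        x = None
        for k in range(request.scale_index):
            h, w = stack.schedule.sizes[k]
            prev = (np.zeros((1, 1, h, w), dtype=ad.DTYPE) if x is None
                    else _upsample_nchw(x, (h, w)))
            if request.reconstruction:
                z = stack.z_rec if k == 0 else np.zeros((1, 1, h, w), dtype=ad.DTYPE)
            else:
                z = (stack.amplitudes[k] *
                     rng.standard_normal((1, 1, h, w))).astype(ad.DTYPE)
            x = _gen_forward(stack.generators[k], Tensor(prev), Tensor(z)).data
        img = np.clip((x[0, 0].astype(np.float64) + 1.0) / 2.0, 0.0, 1.0)
        img = np.clip(_resize01(img, (request.output_size, request.output_size)),
                      0.0, 1.0)
        out.append(img)
    return out


# ---------------------------------------------------------------------
# batch pool driver
# ---------------------------------------------------------------------

def generate_pool(images, per_image: int, config: GanConfig = DESK,
                  seed: int = 0, output_size: int | None = None):
    """Train one stack per source image and sample ``per_image`` outputs
    across the three finest scales of each stack.

    Returns (samples, manifest): the manifest records provenance
    (source image id, scale index, seed, status) for every row; a
    training failure is recorded and the pool continues.
    """
    images = list(images)
    if not images:
        raise ValueError("empty image list")
    if output_size is None:
        output_size = images[0].shape[0]
    rng = np.random.default_rng(seed)
    samples, rows = [], []
    for i, img in enumerate(images):
        train_seed = int(rng.integers(2**31))
        try:
            stack = train_single_image_gan(img, config, seed=train_seed)
        except Exception as exc:  # recorded, pool continues
            rows.append({"sample_id": None, "source_image": i,
                         "scale_index": None, "seed": train_seed,
                         "status": f"train_failed: {exc}"})
            continue
        finest = stack.n_scales
        scales = [max(1, finest - 2), max(1, finest - 1), finest]
        for j in range(per_image):
            sc = scales[j % 3]
            s_seed = int(rng.integers(2**31))
            req = SampleRequest(scale_index=sc, n_samples=1, seed=s_seed,
                                output_size=output_size)
            samples.append(sample(stack, req)[0])
            rows.append({"sample_id": len(samples) - 1, "source_image": i,
                         "scale_index": sc, "seed": s_seed, "status": "ok"})
    return samples, pd.DataFrame(rows)


# ---------------------------------------------------------------------
# (de)serialization: directory of per-scale parameter files + json
# ---------------------------------------------------------------------

def save_stack(stack: GeneratorStack, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cfg = dataclasses.asdict(stack.config)
    (path / "schedule.json").write_text(json.dumps({
        "sizes": [list(s) for s in stack.schedule.sizes],
        "ratio": stack.schedule.ratio,
        "coarse_min_dim": stack.schedule.coarse_min_dim,
        "start_cap": stack.schedule.start_cap,
        "config": cfg,
    }, indent=1))
    (path / "amplitudes.json").write_text(json.dumps({
        "amplitudes": stack.amplitudes, "metrics": stack.metrics,
    }, indent=1))
    np.savez(path / "z_rec.npz", z_rec=stack.z_rec)
    for n, gen in enumerate(stack.generators):
        arrs = {f"p{i}": p.data for i, p in enumerate(gen.params())}
        arrs["recon"] = stack.reconstructions[n]
        np.savez(path / f"scale_{n:02d}.npz", **arrs)


def load_stack(path) -> GeneratorStack:
    path = Path(path)
    meta = json.loads((path / "schedule.json").read_text())
    config = GanConfig(**meta["config"])
    schedule = ScaleSchedule(tuple(tuple(s) for s in meta["sizes"]),
                             meta["ratio"], meta["coarse_min_dim"],
                             meta["start_cap"])
    amps = json.loads((path / "amplitudes.json").read_text())
    stack = GeneratorStack(schedule=schedule, config=config,
                           amplitudes=amps["amplitudes"],
                           metrics=amps["metrics"])
    stack.z_rec = np.load(path / "z_rec.npz")["z_rec"]
    for n in range(schedule.n_scales):
        data = np.load(path / f"scale_{n:02d}.npz")
        gen = _GenNet(config.channels(n), config.n_blocks, config.kernel,
                      np.random.default_rng(0))
        for i, p in enumerate(gen.params()):
            p.data = data[f"p{i}"].astype(ad.DTYPE)
        stack.generators.append(gen)
        stack.reconstructions.append(data["recon"].astype(ad.DTYPE))
    return stack
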