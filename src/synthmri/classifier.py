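"""Class-stratified splitting and a simple convolutional classifier.

The splitter reproduces the reference counts exactly: the per-class
test size is round-half-up of ``n * test_fraction`` (790 at 25% gives
198 test / 592 train; 237 gives 59 / 178).  The classifier is a small
3-block CNN with a sigmoid head, used for conventional-vs-synthetic
discrimination, tumor-vs-normal discrimination, and anomaly screening
(anomaly = tumor) on phantom data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from . import autodiff as ad
from . import nn
from .autodiff import Tensor

__all__ = [
    "SplitSpec", "ClassifierConfig", "BinaryCNN",
    "split_train_test", "train_binary_cnn", "evaluate_accuracy",
    "anomaly_screen",
]


@dataclass(frozen=True)
class SplitSpec:
    """Stratified train/test split specification."""

    test_fraction: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")

    def test_count(self, n: int) -> int:
        """Round-half-up of n * test_fraction, in exact arithmetic."""
        frac = Fraction(self.test_fraction).limit_denominator(10**6)
        return int(n * frac + Fraction(1, 2))  # floor of x + 1/2


def split_train_test(class_items: dict, spec: SplitSpec = SplitSpec()
                     ) -> tuple[dict, dict]:
    """Per class, draw the test set uniformly without replacement;
    the remainder is the train set.  Reproducible by seed."""
    rng = np.random.default_rng(spec.seed)
    train, test = {}, {}
    for cls in sorted(class_items, key=str):
        items = list(class_items[cls])
        if not items:
            raise ValueError(f"class {cls!r} is empty")
        n_test = spec.test_count(len(items))
        idx = rng.permutation(len(items))
        test_idx = set(idx[:n_test].tolist())
        test[cls] = [items[i] for i in range(len(items)) if i in test_idx]
        train[cls] = [items[i] for i in range(len(items)) if i not in test_idx]
    return train, test


# ---------------------------------------------------------------------
# the CNN
# ---------------------------------------------------------------------

@dataclass(frozen=True)
class ClassifierConfig:
    """3 conv blocks (3x3 conv, leaky rectifier, 2x2 pooling) and a
    dense sigmoid head."""

    base_channels: int = 8
    n_blocks: int = 3
    epochs: int = 30
    learning_rate: float = 1e-3
    batch_size: int = 16
    seed: int = 0


@dataclass
class BinaryCNN:
    blocks: list = field(repr=False, default_factory=list)
    w_out: Tensor = field(repr=False, default=None)
    b_out: Tensor = field(repr=False, default=None)
    image_size: int = 0
    config: ClassifierConfig = None
    loss_history: list = field(default_factory=list)

    def params(self):
        out = []
        for b in self.blocks:
            out += b.params()
        return out + [self.w_out, self.b_out]

    def logits(self, imgs: np.ndarray) -> Tensor:
        x = Tensor(imgs[:, None].astype(ad.DTYPE))
        for blk in self.blocks:
            x = ad.avgpool(blk(x), 2)
        n = x.shape[0]
        flat = ad.reshape(x, (n, int(np.prod(x.shape[1:]))))
        return ad.add(ad.matmul(flat, self.w_out),
                      ad.reshape(self.b_out, (1, 1)))

    def predict_proba(self, images) -> np.ndarray:
        imgs = np.stack([np.asarray(i, dtype=np.float64) for i in images])
        probs = []
        for i in range(0, len(imgs), 32):
            z = self.logits(imgs[i:i + 32]).data[:, 0]
            probs.append(1.0 / (1.0 + np.exp(-z)))
        return np.concatenate(probs)


def _build_cnn(image_size: int, config: ClassifierConfig) -> BinaryCNN:
    rng = np.random.default_rng(config.seed)
    blocks, c_in = [], 1
    for b in range(config.n_blocks):
        c_out = config.base_channels * 2 ** b
        blocks.append(nn.ConvBlock(c_in, c_out, rng, norm=True))
        c_in = c_out
    side = image_size // 2 ** config.n_blocks
    feat = c_in * side * side
    w = Tensor(rng.normal(0, 1.0 / np.sqrt(feat), (feat, 1)).astype(ad.DTYPE))
    b = Tensor(np.zeros((1,), dtype=ad.DTYPE))
    return BinaryCNN(blocks=blocks, w_out=w, b_out=b,
                     image_size=image_size, config=config)


def train_binary_cnn(train, config: ClassifierConfig = ClassifierConfig()
                     ) -> BinaryCNN:
    """Train on labeled images: iterable of (image, label) with binary
    labels (0/1 or False/True).  Seed-reproducible; final-epoch loss is
    logged against the first."""
    items = list(train)
    if not items:
        raise ValueError("empty training set")
    imgs = np.stack([np.asarray(im, dtype=np.float64) for im, _ in items])
    labels = np.asarray([float(bool(lab)) for _, lab in items])
    if len(np.unique(labels)) < 2:
        raise ValueError("training set must contain both classes")
    size = imgs.shape[1]
    if imgs.shape[1] != imgs.shape[2] or size % 2 ** config.n_blocks != 0:
        raise ValueError("images must be square with side divisible by "
                         f"{2 ** config.n_blocks}")
    model = _build_cnn(size, config)
    params = model.params()
    opt = nn.Adam(params, lr=config.learning_rate, beta1=0.9)
    rng = np.random.default_rng(config.seed + 1)
    for _epoch in range(config.epochs):
        order = rng.permutation(len(items))
        losses = []
        for i in range(0, len(items), config.batch_size):
            idx = order[i:i + config.batch_size]
            z = model.logits(imgs[idx])
            y = Tensor(labels[idx][:, None].astype(ad.DTYPE))
            loss = nn.bce_with_logits(z, y)
            if not np.isfinite(loss.data):
                raise FloatingPointError("non-finite classifier loss")
            opt.step(ad.grad(loss, params))
            losses.append(float(loss.data))
        model.loss_history.append(float(np.mean(losses)))
    return model


def evaluate_accuracy(model: BinaryCNN, test) -> float:
    """Percent of test items classified correctly at threshold 0.5."""
    items = list(test)
    if not items:
        raise ValueError("empty test set")
    probs = model.predict_proba([im for im, _ in items])
    labels = np.asarray([bool(lab) for _, lab in items])
    calls = probs >= 0.5
    return 100.0 * float((calls == labels).mean())


def anomaly_screen(model: BinaryCNN, images, sources=None
                   ) -> tuple[pd.DataFrame, dict]:
    """Screen images for the anomaly (tumor) class at threshold 0.5.

    ``sources`` optionally tags each image (e.g. 'conventional' vs
    'synthetic') so detection rates can be compared across the two
    pools.  Returns (per-image table, per-source detection rates in
    percent).
    """
    if model.w_out is None:
        raise ValueError("model is untrained")
    images = list(images)
    if sources is None:
        sources = ["all"] * len(images)
    sources = list(sources)
    if len(sources) != len(images):
        raise ValueError("sources must align with images")
    probs = model.predict_proba(images)
    calls = probs >= 0.5
    table = pd.DataFrame({"anomaly_probability": probs, "call": calls,
                          "source": sources})
    rates = {src: 100.0 * float(sub["call"].mean())
             for src, sub in table.groupby("source")}
    return table, rates
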