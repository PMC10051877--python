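"""Shared fixtures.

The two expensive fixtures (the desk-scale GAN stack and the trained
segmenter) are session-scoped so the invariant tests and the acceptance
tests share one training run each.
"""

from __future__ import annotations

import numpy as np
import pytest

import synthmri as s
from synthmri import msgan, prep, segqc

DESK_SIZE = 64


@pytest.fixture(scope="session")
def phantom_params():
    return s.PhantomParams(image_size=DESK_SIZE)


@pytest.fixture(scope="session")
def phantom_volumes(phantom_params):
    """45 phantom volumes, the training cohort scale."""
    rng = np.random.default_rng(100)
    return [s.generate_phantom_volume(phantom_params, 9,
                                      seed=int(rng.integers(2**31)))
            for _ in range(45)]


@pytest.fixture(scope="session")
def training_pairs(phantom_volumes):
    """Three middle contoured slices per volume: 135 (image, mask) pairs."""
    pairs = []
    for vol in phantom_volumes:
        for z in prep.middle_contour_slices(vol, 3):
            pairs.append((vol.slices[z], vol.contours[z]))
    return pairs


@pytest.fixture(scope="session")
def seg_model(training_pairs):
    """Desk-scale segmenter with three metric checkpoints."""
    config = segqc.SegTrainConfig(learning_rate=3e-4, batch_size=3,
                                  steps=400, checkpoint_steps=(50, 200, 400),
                                  base_channels=8, seed=0)
    return segqc.train_segmenter(training_pairs, config)


@pytest.fixture(scope="session")
def desk_stack(phantom_params):
    """Desk-preset single-image GAN trained on one 64x64 phantom."""
    img, _, _ = s.generate_phantom_slice(phantom_params, seed=3)
    return msgan.train_single_image_gan(img, msgan.DESK, seed=11)


@pytest.fixture(scope="session")
def tiny_gan_config():
    """Minutes-to-seconds configuration for determinism/bookkeeping tests."""
    return msgan.GanConfig(base_channels=8, iters_per_scale=20,
                           d_steps=1, g_steps=1)
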