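# Methods

## Overview

The package implements a pipeline for synthesizing 2D prostate-MRI-like
slices with a single-image multi-scale GAN, screening the outputs with
a segmentation-based quality gate, and scoring blinded rater studies of
synthetic-vs-conventional discrimination.  Patient data are replaced
throughout by a parametric phantom with exact ground truth, so every
stage is testable on a laptop CPU.

## The phantom

The phantom emulates the *geometry*, not the texture, of an axial
T2-weighted pelvic slice: dark background (0.02), bright body ellipse
(0.35), mid-intensity prostate (0.55) with a hyperintense peripheral
rim (0.80, thickness 25% of the gland radius), a hyperintense bladder
(0.85) above the gland, and — with probability `lesion_probability` —
a hypointense lesion strictly inside the inner gland (intensity
0.55 − `lesion_contrast`, default contrast 0.30), matching the low T2
signal of tumor against normal prostatic tissue.  Gland radius is drawn
uniformly from 12–22% of the image side.  Nuisance structure is a
multiplicative low-order polynomial bias field (amplitude 0.10) and
additive Gaussian noise (sd 0.03), chosen as the cheapest model that
makes segmentation non-trivial; values are clamped to [0, 1].

Volumes stack slices whose gland radius follows a spherical-cap profile
√(1 − rel²) peaking at the middle slice, with empty contours at the
ends — so "the largest contoured slice" and "the three middle contoured
slices" are well defined exactly as the preprocessing rules need them.
45 volumes × 3 middle slices gives the 135-pair training-set scale the
segmenter expects.

Degenerate variants probe the gate: `no_prostate` omits the gland;
`fragmented` replaces it with 3–4 well-separated blobs (radius 5% of
the image side on a ring of radius 20%), each far below the gate's 4%
area threshold; `blurred` smooths with σ = 9% of the side and collapses
contrast to 0.45 ± 0.15·(x − mean).  The fragment separation and blur
strength were set so the renders actually embody the degeneracy they
name — touching fragments or a mild blur are not degenerate to a
segmentation network and would test nothing.

What the phantom does **not** model: radiological texture, vendor
contrast differences, anatomy beyond the four structures, 3D lesion
growth.  Passing tests therefore demonstrate the pipeline's mechanics
(training dynamics, gating logic, statistics), not clinical realism.

## Single-image multi-scale GAN

**Schedule.**  The finest trained size is the image scaled so its long
side is at most `start_cap` = 250 px; the number of scales is the
smallest N with `fmin · ratio^(N−1) ≤ coarse_min_dim` (ratio 0.75,
coarsest floor 25 px), and intermediate sizes follow the effective
geometric ratio.  A 500×500 image yields exactly 10 scales; scale
indices are 1-based from the coarsest, so "the three finest" of a
10-scale stack are 8, 9, 10.

**Networks.**  Five 3×3 conv blocks per generator and critic
(normalization + leaky rectifier, 0.2 slope; no normalization on the
head block, plain conv tail).  Channels: 32 at the coarsest scale,
doubling every 4 scales (16 in the desk preset).  The generator is
residual: x̃ₙ = prev + Gₙ(prev + zₙ), with tanh output; images live in
[−1, 1] internally.

**Losses.**  Critic: Wasserstein loss D(fake) − D(real) plus a gradient
penalty (‖∇ₓD(x̂)‖ − 1)² at a random interpolate x̂, weight 0.1.
Generator: −D(fake) + α·MSE(reconstruction, real), α = 10.  The
reconstruction path uses one fixed noise map at scale 0 and zero noise
above; its RMSE against the real image at scale n sets the noise
amplitude σₙ = 0.1 · RMSE (σ₀ = 1 by convention).  Adam at 5e-4
(β₁ = 0.5).  Full preset: 2000 iterations/scale with 3 critic and 3
generator steps each; desk preset: 200 iterations with 1/1, which
trains a 64-px phantom stack in a few CPU-minutes while still showing
the qualitative behaviour (reconstruction MSE falls at every scale,
samples are diverse and seed-reproducible).

**Autodiff.**  No GPU framework is used; all networks run on a minimal
reverse-mode engine over numpy (`synthmri.autodiff`) whose
vector-Jacobian products are themselves graph expressions, so the
second derivative needed by the gradient penalty comes out of the same
machinery.  Every primitive and the full penalty path are verified
against central finite differences in the test suite.  Float32 storage;
convolution is im2col + matmul.

## Segmentation and the quality gate

A depth-4 U-Net (channels c, 2c, 4c, 8c with c = 8; average-pool
downsampling, nearest-neighbour upsampling, skip concatenation;
instance normalization) is trained with binary cross-entropy.  The
reference regime (learning rate 1e-5, batch 3, 3000 steps, checkpoints
at 15 epochs / 1000 / 3000 steps) is the config default; the desk
preset used in tests (lr 3e-4, 400 steps, checkpoints 50/200/400)
reaches held-out Dice ≈ 0.99 on phantoms in about half a CPU-minute.
Masks come from thresholding the sigmoid output at 0.5.

The gate passes a predicted mask iff it has **exactly one 8-connected
foreground component** and area ≥ 10,000 px on a 500×500 grid, or ≥ 4%
of the image area at other sizes (the fraction the absolute threshold
corresponds to).  "Single, unbroken boundary" is operationalized as one
connected component; interior holes do not fail the gate, since a
filled region's outer boundary is unbroken regardless of holes.  The
gate is applied to the raw prediction (no largest-component
post-processing).

Percent formatting keeps both conventions found in the reference
values: truncation to one decimal (10,932/250,000 → 4.3) and round half
up (19,481/250,000 → 7.8).  `area_fraction_pct` and `pass_rate` take a
mode argument, defaulting to truncation, and use exact integer
arithmetic so no floating-point tie-breaking is involved.

## Rater-study statistics

The study table is long-format (rater, experience group, image, true
class, answer).  Per group: %correct over all answers; %FP over answers
to conventional images (conventional called synthetic); %FN over
answers to synthetic images; the denominators are rater × class-image
answer counts, the only convention well defined for multi-rater
groups.  Concordance is mean pairwise agreement ×100 (identical to
"proportion of same answers" for two raters).  Reported percentages
are integers, round half up.

Tests: Pearson chi-square without continuity correction; Wilcoxon
signed-rank with zeros dropped and tied ranks averaged (exact null for
≤ 25 untied differences, normal approximation otherwise); two-sample t
with pooled variance by default and a Welch variant.  These delegate to
scipy.stats behind the module surface and are verified against
direct-formula and full-enumeration oracles in the tests.

`simulate_raters` answers each image independently with per-rater
correctness probability a; scoring recovers a within binomial error,
which is the package's parameter-recovery check for the whole scoring
path.

## Splitting and the simple CNN

Stratified splitting draws the per-class test set uniformly without
replacement with test count = round-half-up(n · fraction), computed in
exact rational arithmetic.  This is the only rounding rule consistent
with both reference splits (790 → 198 and 237 → 59 at 25%).

The binary CNN is 3 blocks of (3×3 conv, instance norm, leaky ReLU,
2×2 average pool) with a dense sigmoid head, Adam at 1e-3.  On
phantoms with lesion contrast 0.4 and noise 0.02 it separates
tumor/normal essentially perfectly; with shuffled labels it sits at
chance — the pair of checks that validates the harness rather than any
clinical claim.  Anomaly screening reports detection rates per source
pool so synthetic/conventional parity is a single comparison.

## Numerical choices and degenerate inputs

- Volume normalization is per-volume min-max; a constant volume maps to
  zeros with a warning rather than an error.
- Crop placement is centered (the gland is central in axial pelvic
  MRI); bilinear interpolation for images, nearest-neighbour for masks
  so they stay strictly binary; crop-resize is idempotent on its own
  output.
- Largest-contour ties break to the lowest z index; the "middle k"
  contoured slices center on the lower median for even counts.
- Dice of two empty masks is defined as 1.
- All randomness flows from `numpy.random.default_rng(seed)`; heavier
  drivers split substreams per component, so phantoms, GAN training,
  segmenter training and rater simulation are independently
  reproducible, bit-identically on a given platform.

## Problem sizes used in the checked runs

Phantoms 64×64 (the thresholds are scale-free fractions); GAN desk
preset 200 iterations/scale on a 5-scale 64-px pyramid; segmenter 400
steps on 135 pairs; rater recovery 2000 replicates of a 26
conventional / 34 synthetic design at accuracy 0.67.  These sizes were
chosen so the full suite trains every component from scratch in a few
CPU-minutes; the full-scale presets (500×500, 2000 iterations/scale,
3000 steps) are configuration defaults, exercised structurally but not
trained to convergence in the tests.

## Known limitations

- The phantom's simplicity makes segmentation much easier than on real
  MRI; held-out Dice ≈ 0.99 here says nothing about clinical Dice.
- The GAN's sample quality is not benchmarked (no FID/IS); the tests
  assert training dynamics and sampling contracts, not realism.
- The critic uses instance normalization with the gradient penalty;
  at batch size 1 this is the same per-sample statistic the generator
  uses, and it kept the desk runs stable, but it is a choice, not a
  necessity.
- Exact Wilcoxon p-values are unavailable under ties (the normal
  approximation is used instead), matching common practice.
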