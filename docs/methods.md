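# Methods

This document records the modeling assumptions, parameter conventions, and
numerical choices behind the package, and what the synthetic fixtures do and
do not emulate. Every empirical number quoted here was produced by code in
this repository (the examples or the test suite); no external benchmark
results are claimed.

## Architecture

The network is a five-stage encoder–decoder operating on `H×W×3` inputs
with `H`, `W` divisible by 32 (default 512×512).

**Encoder stage** (one per filter depth in `(8, 16, 32, 48, 64)`):

1. a stem 3×3 convolution + batch norm + ReLU mapping the incoming channels
   to the stage depth;
2. two parallel 3×3 convolution branches — the conventional branch ƛ and
   the graft branch ϑ — each convolution + batch norm + ReLU, both fed from
   the stem output;
3. the element-wise sum `H(x) = ƛ(x) + ϑ(x)`;
4. optionally a squeeze-excitation block (see below);
5. a 3×3, stride-2, same-padded max-pool that halves both spatial extents.

The pre-pool sum `H(x)` is kept as the skip connection for the decoder.
After the fifth pool a single convolution group (conv + BN + ReLU) at depth
64 forms the bottleneck.

**Decoder stage** (depths 64, 48, 32, 16, 8): nearest-neighbour 2×
upsampling, channel concatenation with the matching encoder skip, then one
3×3 convolution + batch norm + ReLU. The head is a 3×3 convolution to one
channel followed by a sigmoid.

All convolutions use "same" padding; spatial extents follow the output-size
formula `⌊(I − f + 2p)/S⌋ + 1`, which the shape tracer applies layer by
layer. The symbolic trace of the default configuration has 81 tabulated
rows, concatenation channel counts 128, 112, 80, 48, 24, a 16×16×64
bottleneck, and a 512×512×1 output, verified against the layer table
shipped as package data (`graftunet/data/table2.json`). The default
configuration has 379,777 trainable parameters, triple-checked against a
closed-form count and a per-row walk of the trace.

**Batch normalization.** The standard formulation
`(x − mean) / sqrt(var + eps)` with per-channel scale and shift, batch
statistics over `N×H×W` during training, and exponential running statistics
(momentum 0.1) at inference. `eps = 1e-5`.

**Squeeze-excitation.** The squeeze is a global *max*-pool over the spatial
extent (not the more common average-pool), followed by a
`c → max(1, c/r) → c` bottleneck MLP (ReLU then sigmoid) whose output gates
the channels multiplicatively. The block is off by default because it is
not part of the tabulated layer sequence; enabling it does not change any
tabulated shape.

## CLAHE

The clip limit follows the slope-based convention

```
beta = (M / N) * (1 + (alpha / 100) * (s_max − 1))
```

with `M` the pixels per tile and `N` the number of gray levels (256). With
`alpha = 0` this is the uniform-histogram floor `M/N`; with `alpha = 100`
the equalization slope is capped at `s_max`. Defaults: 8×8 tiles,
`alpha = 50`, `s_max = 4`.

Clipping is exact integer arithmetic: counts above `ceil(beta)` are clipped,
the excess is redistributed uniformly (remainders go one count at a time to
the lowest-index bins still under the ceiling), iterating until no bin
exceeds the ceiling or every bin sits at it. Histogram mass is conserved
exactly. Each tile's mapping is `round((N−1) · cdf)`; pixels are mapped by
bilinear interpolation between the four neighbouring tile mappings with
clamped tile-centre coordinates, which makes the unclipped configuration
(`alpha = 100`, `s_max = N`) agree pixel-for-pixel with a plain tiled
adaptive-histogram-equalization oracle. Frames whose extents are not
multiples of the tile grid are reflect-padded and cropped back.

By default only the lightness channel of the Lab representation is
equalized (`mode="lab"`), preserving hue; `mode="rgb"` equalizes each
channel independently.

## Metrics

All six metrics are functions of the pixel confusion counts
`(tp, fp, fn, tn)`:

- Dice `2tp / (2tp + fp + fn)`, IoU `tp / (tp + fp + fn)`,
  recall `tp / (tp + fn)`, precision `tp / (tp + fp)`,
  `F2 = 5pr / (4p + r)`, accuracy `(tp + tn) / total`.
- Zero-denominator convention: a ratio whose denominator is zero is defined
  as 1.0 when `fp = fn = 0` (the prediction is vacuously perfect) and 0.0
  otherwise.
- Two aggregations are reported: `per_image_mean` (metric per image, then
  averaged) and `global_counts` (counts pooled over the set, metric once).
  They differ whenever per-image quality varies; the identity
  `Dice = 2·IoU / (1 + IoU)` holds only under `global_counts`.

Predictions are thresholded at 0.5 by default; ground-truth masks must be
strictly binary.

## Training protocol

Defaults: Adam (lr 1e-4, β₁ 0.9, β₂ 0.999), batch size 4, binary
cross-entropy on the sigmoid output (a soft-Dice loss is available), 40
epochs, seeded 70/30 train/test split, 64×64 input for CPU-scale runs. Runs
are deterministic for fixed seeds: weight initialization (He-uniform),
batch shuffling, and the synthetic data are all driven by explicit
generators. Training aborts with epoch context if the loss turns
non-finite. No augmentation, learning-rate schedule, or early stopping is
implemented.

On 80 synthetic 64×64 frames with a 60/20 split, 30 epochs reach per-image
test Dice of 0.93–0.96 across seeds 0–2 on one CPU core (≈45 s per seed);
this is the learnability bar enforced by the test suite (Dice ≥ 0.85 and
better than the all-positive baseline).

## Autodiff engine

A minimal tape-based reverse-mode engine on float32 NumPy arrays in NHWC
layout. Convolution is im2col + matmul (stride 1 only); the input gradient
is computed as a full correlation with the spatially flipped, transposed
kernel, and the weight gradient reuses the cached im2col matrix. Max-pool
gradients scatter into the argmax positions via `np.add.at`. Losses are
fused (`bce_with_logits`, `soft_dice_loss`) for numerical stability; BCE's
gradient is the closed form `(sigmoid(z) − t)/size`, so no large
intermediate `log` terms appear. Gradients of every op are verified against
central finite differences in the test suite.

## Synthetic data

The generator produces frames that exercise the statistics the pipeline
depends on, not photorealistic colonoscopy:

**Emulated:** pink-red mucosa base colour with low-frequency texture; a
dark lumen-like vignette toward a random corner; one to three raised polyp
blobs (Fourier-perturbed ellipses, radial modes 2–4) that are brighter and
redder than their surroundings with dome-like shading; optional specular
highlights (excluded from the mask); Gaussian pixel noise; exact binary
masks stored as 0/255 PNGs with filenames matching the frames.

**Not emulated:** real mucosal vasculature and folds, flat/sessile polyp
morphology and texture, motion blur, fluid and debris, instrument shadows,
interlacing artifacts, realistic illumination falloff, or any
dataset-specific appearance statistics. Segmentation scores obtained on
this data therefore say nothing about clinical performance; they verify
only that the implementation can learn.

Defaults: 64×64 frames, polyp semi-axes 8–25 % of the frame side, minimum
polyp/background contrast 50 gray levels, noise σ 4. All draws come from a
single seeded generator, so datasets are bit-identical across runs.

## Limitations

- Pure NumPy training is CPU-bound; 512×512 training is impractical here.
  The default trainable configuration is 64×64, which preserves the channel
  arithmetic but not the published input scale.
- Stride-1 convolutions only; stride-2 *pooling* covers the published
  downsampling path, but strided convolution variants are unsupported.
- Benchmark-scale results on clinical datasets are out of scope: no
  dataset loaders beyond the paired-folder layout, no augmentation, and no
  GPU path. The package's verifiable claims are architectural conformance,
  formula-level correctness, and learnability on its own fixtures.
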