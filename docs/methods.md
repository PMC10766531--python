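# Methods

## Problem setting

Fluorescence time-lapse microscopy at low photon budgets produces stacks
whose per-pixel intensities are dominated by shot noise (Poisson in the
photon count) plus Gaussian camera read noise. Supervised denoising is
rarely possible — no clean reference exists — and interpolation-style
self-supervision assumes adjacent frames are similar, which fails for
blinking single-molecule data and for volumetric calcium imaging at very low
frame rates. This package trains a denoiser from a single noisy stack by
exploiting *spatial* redundancy instead: adjacent pixels sample nearly the
same optical signal (the point-spread function spans several pixels) but
carry independent noise.

## Orthogonal sampling

Each frame is partitioned into 2×2 blocks. Per block, a center pixel is
drawn uniformly from the four positions (two independent fair bits per
block); the horizontal neighbour within the block differs only in column,
the vertical neighbour only in row. Gathering these choices yields the input
substack `S_c` and targets `S_h`, `S_v` of shape `H/2 × W/2 × T` — a pure
gather, no interpolation. Conventions:

* **One mask per triplet, shared by all `T` frames.** Per-frame masks would
  inject spatial jitter into temporal traces, which the temporal attention
  would then have to model as (spurious) dynamics.
* **Fixed target roles.** The horizontal neighbour always feeds `S_h`, the
  vertical one `S_v`, so each target has a consistent geometric meaning
  (the total loss is symmetric under swapping them anyway).
* **Odd dimensions are cropped**, never padded — padding would fabricate
  intensities that enter the loss.
* Coordinates are 0-based `(row, col, frame)`, row-major; masks are redrawn
  at every extraction call (and hence every epoch), which acts as a mild
  regularizer alongside the eightfold dihedral augmentation.
* Patch origins for training pairs are drawn uniformly with replacement over
  all valid positions across all stacks, with row/column origins restricted
  to even offsets so patches stay aligned with the 2×2 block lattice.

On i.i.d. noise the correlation between `S_c` and either target is ~0 while
real signal correlates strongly — this is the mechanism by which minimizing
the paired loss converges toward the clean signal rather than the noise.

## Network

Three stages, none of which reduces spatial extent:

1. **Temporal encoder module** — two encoders, each compressing the frame
   axis by `r` using a 3×3 spatial convolution over groups of `r`
   consecutive frames treated as channels (`T → T/r → T/r²`), with GELU
   activations. Channel schedule `r → embed/8 → embed` (He-initialized
   convolutions).
2. **Spatiotemporal transformer block (STB)** —
   * *Global attention over patch tokens:* the feature volume is cut into
     `p × p` patches per compressed frame (`p = 7`); each patch slice is
     channel-reduced by a learned 1×1 projection (to `max(embed/32, 4)`
     channels), flattened and linearly embedded to `embed` dimensions.
     Learned spatial (per patch-grid position) and temporal (per compressed
     frame) position embeddings are added, then two cascaded pre-LN
     multi-head self-attention blocks operate over *all* tokens jointly, so
     each location attends to every patch at every time — the receptive
     field is global in space and time after a single STB. The tokens are
     projected back and added residually to the feature volume.
   * *Windowed spatial attention:* a Swin-style pair of sub-blocks (one with
     `p × p` windows, one with windows cyclically shifted by `p/2`) refines
     local structure per compressed frame. The cyclic shift is applied
     without cross-boundary attention masks — a simplification that is
     harmless for denoising and keeps the implementation compact.
3. **Temporal decoder module** — two decoders mirroring the encoders
   (3×3 convolutions expanding channels back into `r` frames each), linear
   output.

**Lightweight choices.** Attention uses an inner (query/key/value) dimension
of `embed/2` and MLP hidden width equal to `embed` (expansion ratio 1).
Together with the channel-reduced patch embedding this keeps the default
configuration (`r=4, p=7`, 8 heads, 128 channels) at ~487 k parameters,
below one tenth of a standard 16-channel-base 3-D U-Net (~5.6 M) — the
test suite counts both analytically.

**Padding.** Frame counts are mirror-padded to a multiple of `r²`
(inputs shorter than `r²/2` frames are rejected — mirroring further would
fabricate periodicity); spatial extents are mirror-padded to multiples of
`p` inside the STB only. All padding is cropped on exit, so output shape
always equals input shape. Position-embedding tables are sized by
`max_patch_grid` (default 12) and `max_time_tokens` (default 16), bounding
the largest tile a single forward pass accepts.

**Initialization.** Truncated normal (σ = 0.02) for projections and
position tables, He-normal for convolutions, zero biases. Inference is
deterministic given fixed weights.

**No deep-learning framework.** The network, backpropagation and Adam run on
a small reverse-mode autodiff engine over NumPy (`srdtrans.nn`). Its
gradients are checked against central finite differences and its Adam update
against hand arithmetic in the unit tests.

## Loss and training

For prediction `F(S_c)` and each target, the loss is the *per-element mean*
squared difference plus the per-element mean absolute difference; the total
is the sum over both targets. Means (rather than raw norms) make the loss
invariant to patch size. Training uses Adam with β₁ = 0.9, β₂ = 0.999 and
default learning rate 1e-5; defaults follow the published recipe
(128×128×128 patches, 6 000 pairs per epoch, eightfold augmentation, batch
size 1 — a free parameter since this implementation targets CPUs). Each
training stack is z-scored; the statistics ride along in every checkpoint
and are inverted at inference. One checkpoint per epoch is written
(`epoch_{k:03d}.ckpt`, a NumPy archive with an embedded config record and
format-version string); the final epoch is the designated inference model.
Gradient norms are logged but never clipped.

## Inference

Full-resolution stacks are denoised in overlapping 3-D tiles; each tile
contributes its central core (half the overlap is discarded per side, except
at stack borders), so stitching is a partition — exactly testable, no
feathering. Because attention context differs between a tile and the whole
stack, tiled and untiled outputs agree exactly only when the stack fits one
tile; otherwise seams are bounded by the attention context difference and
are small relative to the dynamic range. Outputs are clipped at zero
(cameras report nonnegative counts) and written as float32 TIFF (uint16
rescaling opt-in). Volumetric (*xyz–t*) series are reorganized into one
*xy–t* stack per plane and denoised per plane; the reorganization is
bit-exactly invertible.

## Synthetic data

All generators are seeded and bit-reproducible; they emulate the statistical
structure relevant to the denoiser, not the full physics of the instruments.

* **Mixed Poisson–Gaussian noise:** the clean stack is normalized to [0, 1];
  each pixel becomes `Poisson(photon_scale·clean) + N(offset, read_sigma²)`,
  clipped at zero. `calibrate_noise_to_snr` bisects `log₁₀(photon_scale)`
  (read noise tied to `0.5·√photon_scale` so shot and read noise keep a
  fixed proportion) until the measured SNR against the noise-free reference
  is within 0.5 dB of a target.
* **Single-molecule scenes** (default 328×328 px, 30 nm pixels, 200 Hz):
  smooth random filament tracks; per frame a Poisson-distributed number of
  emitters activates at random arc positions, displaced by the 12.5 nm
  linking radius in a random direction, and renders as a 2-D Gaussian PSF
  with σ = 0.21·λ/NA (λ = 670 nm, NA = 1.4 → σ ≈ 100 nm). Photon counts are
  Gamma-distributed around the mean. Ground-truth positions are exact.
  An optional constant background (fraction of the mean emitter peak)
  emulates autofluorescence; it defaults to zero.
  *Not emulated:* blinking photokinetics, 3-D PSF shape, drift.
* **Calcium-like movies** (default 490×490 px, 1.02 µm pixels, 30 Hz):
  elliptical somas with curvilinear neurites; Poisson spike trains convolved
  with an instant-rise, exponential-decay kernel (τ = 0.5 s default) on a
  per-cell baseline plus a static smooth background. Lower rates come from
  frame decimation. *Not emulated:* tissue scattering, motion, indicator
  nonlinearity, correlated activity.
* **Moving objects** (default 512×512 px, 500 objects): procedural 28×28
  thick-stroke glyphs (foreground fraction 0.1–0.3, matching handwritten-
  digit statistics without any download) translating linearly at 0.5
  px/frame with sub-pixel bilinear rendering; each object appears and
  disappears exactly once. Higher speeds are produced by frame decimation,
  never re-rendering.

Because the phantoms are simpler than real tissue, passing tests demonstrate
the *mechanism* (self-supervised denoising from spatial redundancy, correct
metrics, correct plumbing) at desk scale; they do not certify performance on
experimental data or at publication scale.

## Evaluation metrics

* `SNR = 10·log₁₀(‖S_y‖² / ‖S_x − S_y‖²)` (capped at 300 dB when the inputs
  are identical; the reference is used raw, not background-subtracted).
* `SSIM` uses the *global-statistics* form — whole-frame means, variances
  and covariance with `k₁ = 0.01`, `k₂ = 0.03`, `L = 65 535` — not the
  common 11×11 Gaussian-window variant; frames of a stack are averaged.
* `LFD = log₁₀[(1/HW)·Σ‖F_x − F_y‖² + 1]` with the unnormalized 2-D DFT; by
  Parseval this equals `log₁₀(spatial SSD + 1)`, which the tests use as an
  independent oracle.
* Molecule matching is per frame (never across time) via the Hungarian
  algorithm on the 2-D Euclidean distance matrix, with infeasible pairs
  (beyond the matching radius) priced so that the assignment maximizes the
  number of within-radius pairs and, among those, minimizes total distance.
  The radius is not part of the published formulas; the default is 50 nm and
  it is reported in every output table. Degenerate Jaccard (no ground truth
  and no detections) is 100 by convention. `rmse` is undefined (an error,
  never 0) without true positives.
* `Efficiency = 100 − √((100 − Jaccard)² + α²·rmse²)`, α = 1 nm⁻¹.
* `localize_simple` is deliberately minimal plumbing: difference-of-Gaussians
  band-pass, local maxima above a robust-s.d. threshold, least-squares 2-D
  Gaussian refinement in a 7×7 window.

## Desk-scale study conditions for the end-to-end checks

The stochastic end-to-end tests run a *reduced* model: `r = 2`, 32 embedding
channels, 4 heads, 32×32×16 patches, a few hundred Adam steps at lr 1e-3.
`r = 2` (not the full model's 4) keeps the per-compressed-frame channel
budget of the published configuration (128/16 = 32/4 = 8 channels per
frame); with `r = 4` at 32 channels, temporally uncorrelated blinking data
cannot be represented through the bottleneck.

* *Self-supervised efficacy:* a 64×64 px, 240-frame calcium-like movie at
  3 dB input SNR; training on frames 0–191 (300 steps), evaluation on the
  held-out 48 frames; the denoised SNR must exceed the noisy SNR by ≥ 3 dB
  for every seed. Typical gains are 8–10 dB. Published full-scale gains
  (tens of dB averaged over wide SNR ranges) require GPU-scale training and
  are not asserted at desk scale.
* *Localization improvement:* a 64×64 px, 200-frame emitter stack
  (3 filaments, 3 emitters/frame, 1 000 mean photons, background at half the
  mean emitter peak) at 4 dB input SNR; 500 training steps; identical
  localizer settings on raw and denoised data (detection σ 1.6 px — the
  standard default of reference localization software, which is deliberately
  *not* matched to the rendered PSF of σ ≈ 3.35 px — threshold 3 robust
  s.d., an absolute intensity filter at half the expected emitter peak,
  50 nm matching radius). The Jaccard index after denoising must exceed the
  raw-data Jaccard for every seed. Without fluorescent background, a
  PSF-matched band-pass on the raw data is already near the matched-filter
  optimum and denoising cannot improve detection — the background and the
  default-σ filter are what make this benchmark representative of practice.

## Known limitations

* Attention cost grows with tile size and compressed frame count; tiles are
  bounded by the position-table sizes (`max_patch_grid`, `max_time_tokens`).
* The Swin sub-block's cyclic shift is unmasked; for very small tiles the
  shifted windows wrap around the border.
* The checkpoint stores z-score statistics of the *training* stack; applying
  a model to data with a very different intensity scale requires retraining
  or rescaling.
* `localize_simple` is not a full localization package (no multi-emitter
  fitting, no drift correction, no uncertainty estimates).
* Whether the reference training pipeline redraws sampling masks per epoch
  and how it normalizes intensities is not documented; per-epoch redraw and
  per-stack z-scoring are this package's own (tested) conventions.
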