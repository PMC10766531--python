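# srdtrans

Self-supervised denoising of fluorescence time-lapse stacks (*xy–t*) by
**spatial-redundancy orthogonal sampling** and a **lightweight spatiotemporal
transformer** — together with the synthetic-data generators and the full
evaluation-metric suite needed to benchmark it, from pixel-level SNR to
single-molecule localization efficiency.

## Who this is for

Microscopists and image-analysis developers working with low-photon
time-lapse data — single-molecule localization microscopy (SMLM/STORM)
movies, two-photon calcium imaging, volumetric plane series — where no clean
ground truth exists and temporally adjacent frames are *not* similar (fast
blinking emitters, very low volumetric rates), so interpolation-style
self-supervision breaks down.

## The method

**Sampling.** Every frame of a noisy stack of `H × W × T` pixels is divided
into 2×2 blocks. In each block one of the four pixels is drawn uniformly as
the *center*; its horizontal and vertical neighbours inside the block become
the two targets. Gathering these per-block choices over the frame yields
three `H/2 × W/2 × T` substacks `S_c`, `S_h`, `S_v`. Because the optical
signal of adjacent pixels is highly correlated while their shot/read noise is
independent, `(S_c, S_h)` and `(S_c, S_v)` are valid noisy-input/noisy-target
training pairs — no clean data, no temporal similarity required.

**Network.** `F(S_c)` is a transformer with three parts and *no spatial
downsampling anywhere*: two temporal encoders, each compressing the frame
axis by `r = 4` with 3×3 spatial convolutions (so `T → T/r²`); one
spatiotemporal transformer block (STB) in which `p × p × T/r²` patches
(`p = 7`) are embedded into tokens, given learned position embeddings, and
passed through two cascaded multi-head self-attention layers with a global
receptive field in space and time, followed by a windowed (Swin-style)
spatial attention block with one shifted sub-block; and two temporal decoders
restoring the original `T` frames. The default configuration (8 heads,
128 embedding channels) has ~0.49 M parameters — under a tenth of a
16-channel-base 3-D U-Net.

**Loss.** The prediction is pulled towards both targets with a sum of
mean-squared and mean-absolute differences:

```
L_ver   = ||F(S_c) − S_v||²₂ + |F(S_c) − S_v|₁
L_hor   = ||F(S_c) − S_h||²₂ + |F(S_c) − S_h|₁
L_total = L_ver + L_hor
```

optimized with Adam (β₁ = 0.9, β₂ = 0.999, lr = 1e-5 by default); the model
of the last training epoch is used for inference, where the raw
full-resolution stack (never subsampled) is denoised tile by tile.

The package has no deep-learning-framework dependency: the network, its
gradients and the optimizer run on a small reverse-mode autodiff engine over
NumPy (`srdtrans.nn`), verified against finite differences in the test suite.

## Worked example

```python
import numpy as np
import srdtrans as st

# synthesize a calcium-like movie and add camera noise at 3 dB SNR
scene = st.SceneParams(fov_px=64, pixel_size=1.02, frame_rate=30.0,
                       n_frames=240, n_cells=10, spike_rate_hz=0.4, seed=1)
clean, cells = st.simulate_calcium_movie(scene)
noise = st.calibrate_noise_to_snr(clean, target_snr_db=3.0, seed=1)
noisy = st.add_mixed_poisson_gaussian(clean, noise, seed=1001)

# self-supervised training on frames 0..191 (reduced desk-scale model)
model_cfg = st.ModelConfig(r=2, embed_channels=32, heads=4)
train_cfg = st.TrainConfig(lr=1e-3, patch_shape=(32, 32, 16),
                           n_pairs=150, epochs=2, seed=1)
_, ckpt, _ = st.train(st.ImageStack(noisy.data[:, :, :192]), model_cfg, train_cfg)

# denoise the held-out 48 frames and measure the gain
from srdtrans.simulate import expected_signal
ref = expected_signal(clean, noise)[:, :, 192:]
held = noisy.data[:, :, 192:]
den = st.denoise_stack(ckpt, st.ImageStack(held),
                       st.TileConfig((64, 64, 16), (16, 16, 8)))
print(f"input SNR: {st.snr_db(held, ref):.2f} dB")
print(f"output SNR: {st.snr_db(den.data, ref):.2f} dB")
```

Output from this exact script:

```
input SNR: 1.35 dB
output SNR: 10.67 dB
```

The denoiser, trained only on the noisy movie itself, raises the held-out
SNR by ~9.3 dB: the restored frames are ~9× closer (in squared error) to the
noise-free reference than the camera frames were.

The same workflow is available from the shell:

```bash
srdtrans simulate calcium --seed 1 --out clean.tif --noisy noisy.tif --target-snr 3
srdtrans train --input noisy.tif --outdir run/ --seed 1
srdtrans denoise --input noisy.tif --ckpt run/epoch_020.ckpt --output denoised.tif
srdtrans evaluate --pred denoised.tif --gt clean.tif --report report.json
```

Every command writes a JSON run manifest next to its outputs.

## Localization metrics

For SMLM benchmarks the package matches detected molecules to ground truth
per frame with the Hungarian algorithm, then reports the Jaccard index
`100·TP/(TP+FP+FN)`, the r.m.s.e. of matched positions, and the combined
efficiency score `E = 100 − √((100 − Jaccard)² + α²·rmse²)` with α = 1 nm⁻¹.
A minimal band-pass + Gaussian-fit localizer (`st.localize_simple`) makes the
whole pipeline testable end to end.

## Documentation

`docs/methods.md` describes the model assumptions, the synthetic-data
generators and what they do and do not emulate, all numerical choices, and
known limitations.
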