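"""Synthetic-data generators: noise statistics, phantom geometry, kinetics."""

import numpy as np
import pytest

from srdtrans.metrics import pearson_r, snr_db
from srdtrans.simulate import (
    NoiseParams,
    SceneParams,
    add_mixed_poisson_gaussian,
    calibrate_noise_to_snr,
    decimate_frames,
    expected_signal,
    simulate_calcium_movie,
    simulate_emitter_stack,
    simulate_moving_objects,
    _render_gaussian_spots,
)
from srdtrans.stack import ImageStack


# ---- mixed Poisson-Gaussian noise -------------------------------------------


def test_high_photon_limit_recovers_clean(rng):
    clean = rng.random((32, 32, 4)) + 0.1
    params = NoiseParams(photon_scale=1e6, read_sigma=0.0)
    noisy = add_mixed_poisson_gaussian(clean, params, seed=0)
    ref = expected_signal(clean, params)
    rel_rms = np.sqrt(np.mean((noisy.data - ref) ** 2)) / ref.mean()
    assert rel_rms < 0.002  # Poisson concentration: relative noise ~ 1/sqrt(1e6)


def test_noise_is_unbiased():
    clean = np.full((100, 100, 1), 0.5)
    clean[0, 0, 0] = 1.0  # pins the internal [0, 1] normalization
    params = NoiseParams(photon_scale=50.0, read_sigma=2.0, offset=10.0)
    noisy = add_mixed_poisson_gaussian(clean, params, seed=1)
    body = noisy.data.ravel()[1:]  # the 0.5-valued pixels
    # mean of (noisy - offset) ~ photon_scale * clean within 3 s.e. over 1e4 px
    per_pixel_var = 50.0 * 0.5 + 4.0
    se = np.sqrt(per_pixel_var / body.size)
    assert abs((body.mean() - 10.0) - 25.0) < 3 * se + 0.05  # +0.05 for zero clipping


def test_noise_reproducible_and_negative_rejected(rng):
    clean = rng.random((8, 8, 2))
    p = NoiseParams(photon_scale=100.0, read_sigma=1.0)
    a = add_mixed_poisson_gaussian(clean, p, seed=3)
    b = add_mixed_poisson_gaussian(clean, p, seed=3)
    np.testing.assert_array_equal(a.data, b.data)
    with pytest.raises(ValueError, match="negative"):
        add_mixed_poisson_gaussian(clean - 0.5, p, seed=0)


def test_snr_decreases_along_noise_ladder(rng):
    clean = rng.random((32, 32, 8)) + 0.05
    snrs = []
    for scale in (3000.0, 1000.0, 300.0, 100.0, 30.0):
        params = NoiseParams(photon_scale=scale, read_sigma=0.5 * np.sqrt(scale))
        noisy = add_mixed_poisson_gaussian(clean, params, seed=7)
        snrs.append(snr_db(noisy.data, expected_signal(clean, params)))
    assert all(a > b for a, b in zip(snrs, snrs[1:]))


def test_calibration_closed_loop(rng):
    clean = rng.random((48, 48, 6)) + 0.1
    params = calibrate_noise_to_snr(clean, 10.0, seed=2)
    noisy = add_mixed_poisson_gaussian(clean, params, seed=2)
    assert snr_db(noisy.data, expected_signal(clean, params)) == pytest.approx(10.0, abs=0.5)
    high = calibrate_noise_to_snr(clean, 60.0, seed=2)  # high-photon limit is reachable
    assert high.photon_scale > params.photon_scale
    with pytest.raises(ValueError, match="achievable"):
        calibrate_noise_to_snr(clean, -60.0, seed=2)


# ---- emitter scenes -----------------------------------------------------------


def test_zero_density_gives_black_stack():
    sp = SceneParams(fov_px=32, n_frames=5, emitters_per_frame=0.0, seed=0)
    stack, molecules = simulate_emitter_stack(sp)
    assert stack.data.max() == 0.0
    assert len(molecules) == 0


def test_rendered_spot_centroid_matches_ground_truth():
    frame = _render_gaussian_spots((33, 33), np.array([16.0]), np.array([16.0]), np.array([1000.0]), 3.35)
    rr, cc = np.mgrid[0:33, 0:33]
    cy = (frame * rr).sum() / frame.sum()
    cx = (frame * cc).sum() / frame.sum()
    assert abs(cx - 16.0) < 0.01 and abs(cy - 16.0) < 0.01


def test_emitter_counts_have_poisson_dispersion():
    sp = SceneParams(fov_px=32, n_frames=500, n_filaments=3, emitters_per_frame=5.0, seed=4)
    _, molecules = simulate_emitter_stack(sp)
    counts = np.bincount(molecules.frame, minlength=500)
    ratio = counts.var() / counts.mean()
    assert 0.8 < ratio < 1.2


def test_emitters_reproducible_and_inside_fov():
    sp = SceneParams(fov_px=32, n_frames=20, n_filaments=2, emitters_per_frame=4.0, seed=9)
    s1, m1 = simulate_emitter_stack(sp)
    s2, m2 = simulate_emitter_stack(sp)
    np.testing.assert_array_equal(s1.data, s2.data)
    np.testing.assert_array_equal(m1.x_nm, m2.x_nm)
    fov_nm = 32 * sp.pixel_size
    margin = 2 * sp.linking_radius_nm
    assert np.all(m1.x_nm > -margin) and np.all(m1.x_nm < fov_nm + margin)
    assert np.all(m1.photons > 0)


# ---- calcium scenes -----------------------------------------------------------


def test_zero_spike_rate_gives_static_movie():
    sp = SceneParams(fov_px=48, pixel_size=1.02, frame_rate=30.0, n_frames=40,
                     n_cells=4, spike_rate_hz=0.0, seed=1)
    stack, gt = simulate_calcium_movie(sp)
    assert np.ptp(stack.data, axis=2).max() == pytest.approx(0.0, abs=1e-6)
    assert all(len(s) == 0 for s in gt.spikes)


def test_transient_decay_time_constant():
    """A single isolated spike decays with the configured time constant."""
    sp = SceneParams(fov_px=48, pixel_size=1.02, frame_rate=30.0, n_frames=400,
                     n_cells=1, spike_rate_hz=0.1, tau_decay_s=0.5, seed=3)
    _, gt = simulate_calcium_movie(sp)
    spikes = gt.spikes[0]
    assert len(spikes) >= 1
    k0 = int(spikes[0])
    end = int(spikes[1]) if len(spikes) > 1 else 400
    seg = gt.traces[0, k0 : min(k0 + 90, end)]
    baseline = gt.traces[0, k0 - 1] if k0 > 0 else float(gt.traces[0].min())
    decay = seg - baseline
    decay = decay[decay > 0.05 * decay[0]]
    tau_frames_fit = -1.0 / np.polyfit(np.arange(len(decay)), np.log(decay), 1)[0]
    assert tau_frames_fit == pytest.approx(0.5 * 30.0, rel=0.10)


def test_mask_trace_consistency():
    """The movie, averaged over a cell mask, reproduces that cell's trace."""
    sp = SceneParams(fov_px=64, pixel_size=1.02, frame_rate=30.0, n_frames=120,
                     n_cells=5, spike_rate_hz=0.5, seed=6)
    stack, gt = simulate_calcium_movie(sp)
    overlap = gt.masks.reshape(5, -1) @ gt.masks.reshape(5, -1).T
    for i in range(5):
        others = [j for j in range(5) if j != i]
        if overlap[i, others].max() > 0.01 * overlap[i, i]:
            continue  # only non-overlapping cells give clean traces
        w = gt.masks[i]
        extracted = np.einsum("hw,hwt->t", w, stack.data) / w.sum()
        assert pearson_r(extracted, gt.traces[i]) > 0.99


def test_cell_placement_failure_raises():
    with pytest.raises(ValueError, match="place"):
        simulate_calcium_movie(SceneParams(fov_px=24, n_frames=4, n_cells=40, seed=0))


# ---- moving objects ------------------------------------------------------------


def test_moving_object_speed_via_centroid():
    sp = SceneParams(fov_px=128, pixel_size=1.0, frame_rate=30.0, n_frames=40,
                     n_objects=1, speed_px_per_frame=0.5, seed=1)
    stack, table = simulate_moving_objects(sp)
    frames = sorted(table["frame"].unique())
    assert len(frames) >= 12  # the object is visible long enough to track
    cents = []
    for k in frames[:12]:
        img = stack.data[:, :, k]
        rr, cc = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
        cents.append((float((img * rr).sum() / img.sum()), float((img * cc).sum() / img.sum())))
    steps = [np.hypot(a[0] - b[0], a[1] - b[1]) for a, b in zip(cents, cents[1:])]
    assert np.allclose(steps, 0.5, atol=0.01)
    # decimation multiplies the effective speed: 0.5 px/frame x 4 = 2 px/frame
    dec = decimate_frames(stack, 4)
    assert dec.data.shape[2] == int(np.ceil(stack.data.shape[2] / 4))
    rows = table[table["frame"].isin([frames[0], frames[4]])].sort_values("frame")
    disp = np.hypot(rows["row_px"].diff().iloc[-1], rows["col_px"].diff().iloc[-1])
    assert disp == pytest.approx(4 * 0.5, abs=0.01)


def test_object_count_honored():
    sp = SceneParams(fov_px=96, n_frames=6, n_objects=17, speed_px_per_frame=1.0, seed=2)
    _, table = simulate_moving_objects(sp)
    assert table["object"].nunique() == 17


def test_glyph_statistics():
    from srdtrans.simulate import _procedural_glyph

    rng = np.random.default_rng(0)
    fracs = [float(_procedural_glyph(rng).mean()) for _ in range(20)]
    assert all(0.05 <= f <= 0.35 for f in fracs)  # thick strokes, mostly background


# ---- frame decimation -----------------------------------------------------------


def test_decimation_identity_and_metadata(rng):
    stack = ImageStack(rng.random((8, 8, 100)).astype(np.float32), frame_rate=30.0)
    same = decimate_frames(stack, 1)
    np.testing.assert_array_equal(same.data, stack.data)
    one = decimate_frames(stack, 100)
    assert one.data.shape[2] == 1
    np.testing.assert_array_equal(one.data[:, :, 0], stack.data[:, :, 0])
    low = decimate_frames(stack, 100)
    assert low.frame_rate == pytest.approx(0.3)
    with pytest.raises(ValueError):
        decimate_frames(stack, 0)
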