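"""Evaluation metrics: hand examples, independent oracles, matching correctness."""

import itertools

import numpy as np
import pytest

from srdtrans.metrics import (
    SNR_CAP_DB,
    SSIM_K1,
    SSIM_K2,
    SSIM_L,
    efficiency,
    jaccard_pct,
    lfd,
    localize_simple,
    match_molecules,
    pearson_r,
    rmse_nm,
    snr_db,
    ssim,
)
from srdtrans.molecules import MoleculeSet
from srdtrans.simulate import _render_gaussian_spots


# ---- SNR ----------------------------------------------------------------------


def test_snr_hand_example():
    y = np.array([[1.0, 2.0], [2.0, 1.0]])
    x = y.copy()
    x[0, 0] += 1.0
    assert snr_db(x, y) == pytest.approx(10.0)  # 10*log10(10/1)


def test_snr_identical_hits_cap(rng):
    a = rng.random((8, 8))
    assert snr_db(a, a) == SNR_CAP_DB


def test_snr_residual_scaling(rng):
    y = rng.random((16, 16)) + 0.5
    e = rng.normal(size=y.shape) * 0.01
    drop = snr_db(y + e, y) - snr_db(y + 2 * e, y)
    assert drop == pytest.approx(20 * np.log10(2), abs=1e-9)


def test_snr_errors(rng):
    with pytest.raises(ValueError, match="zero"):
        snr_db(rng.random((4, 4)), np.zeros((4, 4)))
    with pytest.raises(ValueError, match="shape"):
        snr_db(rng.random((4, 4)), rng.random((5, 4)))


# ---- SSIM ----------------------------------------------------------------------


def test_ssim_identity(rng):
    a = rng.random((12, 12)) * 500
    assert ssim(a, a) == pytest.approx(1.0)


def test_ssim_constant_images_collapse_to_luminance_term():
    a, b = 3.0, 5.0
    c1 = (SSIM_K1 * SSIM_L) ** 2
    expected = (2 * a * b + c1) / (a**2 + b**2 + c1)
    assert ssim(np.full((6, 6), a), np.full((6, 6), b)) == pytest.approx(expected, rel=1e-12)


def test_ssim_against_independent_direct_evaluation(rng):
    """Second, independently coded evaluation of the global-statistics formula."""
    for _ in range(10):
        x, y = rng.random((9, 11)) * 100, rng.random((9, 11)) * 100
        c1 = (0.01 * 65535.0) ** 2
        c2 = (0.03 * 65535.0) ** 2
        mx, my = np.mean(x), np.mean(y)
        sxy = np.mean(x * y) - mx * my
        vx = np.mean(x * x) - mx * mx
        vy = np.mean(y * y) - my * my
        direct = ((2 * mx * my + c1) * (2 * sxy + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2))
        assert ssim(x, y) == pytest.approx(direct, abs=1e-12)


# ---- Pearson R ------------------------------------------------------------------


def test_pearson_basics(rng):
    x = rng.random((7, 7))
    assert pearson_r(x, x) == pytest.approx(1.0)
    assert pearson_r(x, -x) == pytest.approx(-1.0)
    assert pearson_r(x, 2 * x + 3) == pytest.approx(1.0)  # affine invariance
    with pytest.raises(ValueError, match="constant"):
        pearson_r(np.full((4, 4), 2.0), x[:4, :4])


# ---- LFD -------------------------------------------------------------------------


def test_lfd_identity_and_hand_example(rng):
    a = rng.random((8, 8))
    assert lfd(a, a) == 0.0
    x = np.zeros((2, 2))
    y = x.copy()
    y[0, 1] = 3.0
    assert lfd(x, y) == pytest.approx(1.0)  # log10(9 + 1) by Parseval


def test_lfd_parseval_equivalence(rng):
    """The frequency-domain definition equals log10(spatial SSD + 1) exactly."""
    for _ in range(20):
        h, w = rng.integers(3, 20, size=2)
        x, y = rng.random((2, h, w)) * 10
        ssd = float(((x - y) ** 2).sum())
        assert lfd(x, y) == pytest.approx(np.log10(ssd + 1.0), abs=1e-9)


# ---- Hungarian matching -----------------------------------------------------------


def _brute_force_best(dpos, gpos, radius):
    """Exhaustive assignment: maximize pairs within radius, then minimize distance."""
    nd, ng = len(dpos), len(gpos)
    best = (0, 0.0)
    best_count, best_cost = 0, np.inf
    for k in range(min(nd, ng), -1, -1):
        if k < best_count:
            break
        for dsub in itertools.permutations(range(nd), k):
            for gsub in itertools.combinations(range(ng), k):
                dist = [np.linalg.norm(dpos[i] - gpos[j]) for i, j in zip(dsub, gsub)]
                if all(d <= radius for d in dist):
                    if k > best_count or (k == best_count and sum(dist) < best_cost):
                        best_count, best_cost = k, sum(dist)
    return best_count, best_cost


def test_matching_equals_brute_force(rng):
    for _ in range(30):
        nd, ng = rng.integers(0, 6, size=2)
        dpos = rng.random((nd, 2)) * 100
        gpos = rng.random((ng, 2)) * 100
        det = MoleculeSet(np.zeros(nd, int), dpos[:, 0], dpos[:, 1], np.ones(nd))
        gt = MoleculeSet(np.zeros(ng, int), gpos[:, 0], gpos[:, 1], np.ones(ng))
        m = match_molecules(det, gt, radius_nm=30.0)
        count, cost = _brute_force_best(dpos, gpos, 30.0)
        assert m.tp == count
        if count:
            assert sum(m.distances_nm) == pytest.approx(cost, abs=1e-9)


def test_matching_exact_and_empty():
    gt = MoleculeSet(np.zeros(5, int), np.arange(5) * 100.0, np.zeros(5), np.ones(5))
    m = match_molecules(gt, gt, radius_nm=10.0)
    assert m.tp == 5 and m.fp == 0 and m.fn == 0
    assert np.all(m.distances_nm == 0.0)
    m2 = match_molecules(MoleculeSet(), gt, radius_nm=10.0)
    assert (m2.tp, m2.fp, m2.fn) == (0, 0, 5)


def test_matching_respects_frames():
    a = MoleculeSet(np.array([0]), np.array([0.0]), np.array([0.0]), np.array([1.0]))
    b = MoleculeSet(np.array([1]), np.array([0.0]), np.array([0.0]), np.array([1.0]))
    m = match_molecules(a, b, radius_nm=50.0)
    assert m.tp == 0 and m.fp == 1 and m.fn == 1  # same position, different frames


# ---- Jaccard / r.m.s.e. / efficiency -------------------------------------------------


def _mk_match(tp_dists, fp, fn):
    from srdtrans.metrics import MatchResult

    return MatchResult(tp_pairs=[(i, i, d) for i, d in enumerate(tp_dists)], fp=fp, fn=fn)


def test_jaccard_examples():
    assert jaccard_pct(_mk_match([0.0], 0, 0)) == 100.0
    assert jaccard_pct(_mk_match([1.0, 2.0], 1, 1)) == 50.0
    assert jaccard_pct(_mk_match([], 3, 7)) == 0.0
    assert jaccard_pct(_mk_match([], 0, 0)) == 100.0  # degenerate case, by convention


def test_rmse_examples():
    assert rmse_nm(_mk_match([0.0, 0.0], 0, 0)) == 0.0
    assert rmse_nm(_mk_match([3.0, 4.0], 0, 0)) == pytest.approx(np.sqrt(12.5))
    with pytest.raises(ValueError, match="undefined"):
        rmse_nm(_mk_match([], 2, 2))


def test_efficiency_examples_and_monotonicity():
    assert efficiency(100.0, 0.0) == 100.0
    assert efficiency(85.7, 24.86) == pytest.approx(71.33, abs=0.05)
    assert efficiency(14.1, 85.94) == pytest.approx(-21.54, abs=0.1)
    assert efficiency(90.0, 10.0) > efficiency(80.0, 10.0)
    assert efficiency(90.0, 10.0) > efficiency(90.0, 20.0)
    with pytest.raises(ValueError):
        efficiency(101.0, 5.0)


# ---- spot localizer --------------------------------------------------------------------


def test_localize_blank_frame():
    assert len(localize_simple(np.zeros((32, 32)), pixel_size_nm=30.0)) == 0


def test_localize_recovers_subpixel_position():
    frame = _render_gaussian_spots((33, 33), np.array([15.63]), np.array([17.27]), np.array([1000.0]), 3.35)
    det = localize_simple(frame, pixel_size_nm=30.0, detect_sigma_px=3.35, threshold_sd=4.0)
    assert len(det) == 1
    assert abs(det.x_nm[0] / 30.0 - 15.63) < 0.05
    assert abs(det.y_nm[0] / 30.0 - 17.27) < 0.05


def test_localize_two_separated_spots():
    frame = _render_gaussian_spots(
        (40, 40), np.array([14.0, 24.0]), np.array([20.0, 20.0]), np.array([1000.0, 1000.0]), 2.0
    )
    det = localize_simple(frame, pixel_size_nm=30.0, detect_sigma_px=2.0, threshold_sd=4.0)
    assert len(det) == 2
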