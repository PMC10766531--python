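"""Evaluation metrics for denoising and single-molecule localization.

Image-level: SNR (dB), SSIM (global statistics per frame), Pearson R, and
the logarithmic frequency distance (LFD).  Localization-level: Hungarian
ground-truth matching, Jaccard index, r.m.s.e. of matched positions, and the
combined efficiency score

    E = 100 - sqrt((100 - Jaccard)^2 + alpha^2 * rmse^2),  alpha = 1 /nm.

A minimal band-pass/Gaussian-fit spot localizer is included so the whole
localization pipeline is testable end to end.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.optimize import least_squares, linear_sum_assignment

from .molecules import MoleculeSet

__all__ = [
    "MatchResult",
    "MetricReport",
    "snr_db",
    "ssim",
    "pearson_r",
    "lfd",
    "match_molecules",
    "jaccard_pct",
    "rmse_nm",
    "efficiency",
    "localize_simple",
    "SNR_CAP_DB",
    "SSIM_K1",
    "SSIM_K2",
    "SSIM_L",
]

SNR_CAP_DB = 300.0
SSIM_K1 = 0.01
SSIM_K2 = 0.03
SSIM_L = 65535.0


def _as_float(x) -> np.ndarray:
    from .stack import ImageStack

    if isinstance(x, ImageStack):
        x = x.data
    return np.asarray(x, dtype=np.float64)


def _check_shapes(x: np.ndarray, y: np.ndarray) -> None:
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")


def snr_db(x, y) -> float:
    """10 log10(||y||^2 / ||x - y||^2); capped at 300 dB when x == y."""
    x, y = _as_float(x), _as_float(y)
    _check_shapes(x, y)
    sig = float((y**2).sum())
    if sig == 0:
        raise ValueError("ground truth is all zeros: SNR undefined")
    res = float(((x - y) ** 2).sum())
    if res == 0:
        return SNR_CAP_DB
    return min(10.0 * np.log10(sig / res), SNR_CAP_DB)


def _ssim_frame(x: np.ndarray, y: np.ndarray) -> float:
    c1 = (SSIM_K1 * SSIM_L) ** 2
    c2 = (SSIM_K2 * SSIM_L) ** 2
    mx, my = x.mean(), y.mean()
    vx, vy = x.var(), y.var()
    cov = ((x - mx) * (y - my)).mean()
    return float(((2 * mx * my + c1) * (2 * cov + c2)) / ((mx**2 + my**2 + c1) * (vx + vy + c2)))


def ssim(x, y) -> float:
    """Whole-frame-statistics SSIM, averaged over frames for stacks."""
    x, y = _as_float(x), _as_float(y)
    _check_shapes(x, y)
    if x.ndim == 2:
        return _ssim_frame(x, y)
    if x.ndim == 3:
        return float(np.mean([_ssim_frame(x[:, :, k], y[:, :, k]) for k in range(x.shape[2])]))
    raise ValueError("ssim expects a 2-D image or 3-D stack")


def pearson_r(x, y) -> float:
    """Product-moment correlation over all elements."""
    x, y = _as_float(x).ravel(), _as_float(y).ravel()
    _check_shapes(x, y)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(np.corrcoef(x, y)[0, 1])


def _lfd_frame(x: np.ndarray, y: np.ndarray) -> float:
    H, W = x.shape
    fx = np.fft.fft2(x)  # unnormalized DFT
    fy = np.fft.fft2(y)
    return float(np.log10((np.abs(fx - fy) ** 2).sum() / (H * W) + 1.0))


def lfd(x, y) -> float:
    """Logarithmic frequency distance, per frame; stack mean for 3-D input."""
    x, y = _as_float(x), _as_float(y)
    _check_shapes(x, y)
    if x.ndim == 2:
        return _lfd_frame(x, y)
    if x.ndim == 3:
        return float(np.mean([_lfd_frame(x[:, :, k], y[:, :, k]) for k in range(x.shape[2])]))
    raise ValueError("lfd expects a 2-D image or 3-D stack")


@dataclass
class MetricReport:
    snr_db: float
    ssim: float
    pearson_r: float
    lfd: float

    def to_dict(self) -> dict:
        return {"snr_db": self.snr_db, "ssim": self.ssim, "pearson_r": self.pearson_r, "lfd": self.lfd}


def evaluate_images(pred, gt) -> MetricReport:
    return MetricReport(snr_db=snr_db(pred, gt), ssim=ssim(pred, gt), pearson_r=pearson_r(pred, gt), lfd=lfd(pred, gt))


# ----- localization matching ---------------------------------------------------


@dataclass
class MatchResult:
    """TP pairings with distances plus FP/FN counts, accumulated per frame."""

    tp_pairs: list[tuple[int, int, float]] = field(default_factory=list)  # (det idx, gt idx, nm)
    fp: int = 0
    fn: int = 0
    radius_nm: float = 0.0

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def distances_nm(self) -> np.ndarray:
        return np.array([d for _, _, d in self.tp_pairs])


def match_molecules(detected: MoleculeSet, gt: MoleculeSet, radius_nm: float = 50.0) -> MatchResult:
    """Hungarian one-to-one matching per frame within a distance radius.

    The assignment maximizes the number of pairs within the radius and,
    among those, minimizes the total distance.  Unmatched detections are
    false positives; unmatched ground-truth molecules are false negatives.
    Frames never match across time.
    """
    if radius_nm <= 0:
        raise ValueError("matching radius must be positive")
    result = MatchResult(radius_nm=radius_nm)
    frames = np.union1d(np.unique(detected.frame), np.unique(gt.frame))
    det_index = np.arange(len(detected))
    gt_index = np.arange(len(gt))
    for k in frames:
        dsel = det_index[detected.frame == k]
        gsel = gt_index[gt.frame == k]
        if len(dsel) == 0:
            result.fn += len(gsel)
            continue
        if len(gsel) == 0:
            result.fp += len(dsel)
            continue
        dpos = np.stack([detected.x_nm[dsel], detected.y_nm[dsel]], axis=1)
        gpos = np.stack([gt.x_nm[gsel], gt.y_nm[gsel]], axis=1)
        dist = np.linalg.norm(dpos[:, None, :] - gpos[None, :, :], axis=2)
        # infeasible pairs get a cost so large that any feasible pair is
        # preferred over saving distance elsewhere
        big = radius_nm * (len(dsel) + len(gsel) + 1) * 1000.0
        cost = np.where(dist <= radius_nm, dist, big)
        rows, cols = linear_sum_assignment(cost)
        matched_d, matched_g = set(), set()
        for i, j in zip(rows, cols):
            if dist[i, j] <= radius_nm:
                result.tp_pairs.append((int(dsel[i]), int(gsel[j]), float(dist[i, j])))
                matched_d.add(i)
                matched_g.add(j)
        result.fp += len(dsel) - len(matched_d)
        result.fn += len(gsel) - len(matched_g)
    return result


def jaccard_pct(m: MatchResult) -> float:
    """100 * TP / (TP + FP + FN); 100 by convention when all three are zero."""
    denom = m.tp + m.fp + m.fn
    if denom == 0:
        return 100.0
    return 100.0 * m.tp / denom


def rmse_nm(m: MatchResult) -> float:
    """Root-mean-square distance of matched pairs; undefined without TPs."""
    if m.tp == 0:
        raise ValueError("r.m.s.e. undefined with zero true positives")
    return float(np.sqrt(np.mean(m.distances_nm**2)))


def efficiency(jaccard: float, rmse: float, alpha_per_nm: float = 1.0) -> float:
    """Combined detection/precision score: 100 - sqrt((100-J)^2 + a^2 rmse^2)."""
    if not (0.0 <= jaccard <= 100.0):
        raise ValueError("Jaccard index must be in [0, 100]")
    if rmse < 0:
        raise ValueError("rmse must be nonnegative")
    return 100.0 - float(np.sqrt((100.0 - jaccard) ** 2 + alpha_per_nm**2 * rmse**2))


# ----- minimal spot localizer ---------------------------------------------------


def _gauss2d_residual(params, rr, cc, z):
    amp, r0, c0, sigma, bg = params
    model = amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2)) + bg
    return (model - z).ravel()


def localize_simple(
    frame: np.ndarray,
    pixel_size_nm: float,
    detect_sigma_px: float = 3.0,
    threshold_sd: float = 4.0,
    fit_window: int = 7,
) -> MoleculeSet:
    """Band-pass + local-maximum detection with sub-pixel Gaussian refinement.

    A difference-of-Gaussians filter suppresses background and pixel noise;
    local maxima above ``threshold_sd`` robust standard deviations of the
    filtered background are refined by least-squares 2-D Gaussian fits in a
    ``fit_window`` x ``fit_window`` region.  Positions are returned in nm
    (x = column, y = row), all with frame index 0.
    """
    z = np.asarray(frame, dtype=np.float64)
    if z.ndim != 2:
        raise ValueError("localize_simple expects a single 2-D frame")
    if z.max() == z.min():
        if z.max() > 0:
            warnings.warn("saturated flat frame: no localizations possible")
        return MoleculeSet()
    bp = ndimage.gaussian_filter(z, detect_sigma_px * 0.6) - ndimage.gaussian_filter(z, detect_sigma_px * 2.5)
    mad = np.median(np.abs(bp - np.median(bp)))
    noise_sd = 1.4826 * mad if mad > 0 else bp.std()
    thresh = np.median(bp) + threshold_sd * noise_sd
    maxima = (ndimage.maximum_filter(bp, size=max(int(2 * detect_sigma_px) | 1, 3)) == bp) & (bp > thresh)
    half = fit_window // 2
    rows, cols, amps = [], [], []
    for r, c in zip(*np.nonzero(maxima)):
        r0, r1 = r - half, r + half + 1
        c0, c1 = c - half, c + half + 1
        if r0 < 0 or c0 < 0 or r1 > z.shape[0] or c1 > z.shape[1]:
            continue
        win = z[r0:r1, c0:c1]
        rr, cc = np.mgrid[r0:r1, c0:c1].astype(float)
        p0 = [win.max() - win.min(), float(r), float(c), detect_sigma_px / 2, win.min()]
        try:
            res = least_squares(
                _gauss2d_residual, p0, args=(rr, cc, win),
                bounds=([0, r0, c0, 0.3, -np.inf], [np.inf, r1, c1, fit_window, np.inf]),
                max_nfev=200,
            )
        except ValueError:
            continue
        amp, rf, cf, _, _ = res.x
        if amp <= 0:
            continue
        rows.append(rf)
        cols.append(cf)
        amps.append(amp)
    n = len(rows)
    return MoleculeSet(
        frame=np.zeros(n, dtype=int),
        x_nm=np.array(cols) * pixel_size_nm,
        y_nm=np.array(rows) * pixel_size_nm,
        photons=np.array(amps),
    )


def localize_stack(
    stack, pixel_size_nm: float, detect_sigma_px: float = 3.0, threshold_sd: float = 4.0
) -> MoleculeSet:
    """Run :func:`localize_simple` on every frame of a stack."""
    from .stack import ImageStack

    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    sets = []
    for k in range(data.shape[2]):
        s = localize_simple(data[:, :, k], pixel_size_nm, detect_sigma_px, threshold_sd)
        s.frame[:] = k
        sets.append(s)
    return MoleculeSet.concatenate(sets)
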