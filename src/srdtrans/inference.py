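"""Full-resolution denoising of arbitrarily large stacks.

The raw noisy stack is *not* spatially subsampled at inference: tiles of the
full-resolution data are normalized with the checkpoint statistics, pushed
through the trained network, denormalized, and stitched by central cropping
(each tile contributes only its core region, half the overlap away from the
tile border, so tiles never blend and stitching is exactly testable).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model import Checkpoint, load_checkpoint
from .stack import ImageStack

__all__ = ["TileConfig", "denoise_stack", "reorganize_volumetric", "assemble_volumetric"]


@dataclass(frozen=True)
class TileConfig:
    """Tile extents and per-axis overlap (rows, cols, frames)."""

    tile_shape: tuple[int, int, int] = (256, 256, 16)
    overlap: tuple[int, int, int] = (16, 16, 8)

    def __post_init__(self):
        for t, o in zip(self.tile_shape, self.overlap):
            if o >= t:
                raise ValueError(f"overlap {self.overlap} must be smaller than tile {self.tile_shape}")
            if o % 2:
                raise ValueError("overlaps must be even (central-crop stitching halves them)")


def _tile_starts(length: int, tile: int, overlap: int) -> list[int]:
    if length <= tile:
        return [0]
    stride = tile - overlap
    starts = list(range(0, length - tile, stride))
    starts.append(length - tile)
    return starts


def denoise_stack(
    ckpt: Checkpoint | str | Path | object,
    stack: ImageStack | np.ndarray,
    tiles: TileConfig = TileConfig(),
) -> ImageStack:
    """Denoise a stack with a trained checkpoint (or any predict-capable model).

    Output shape equals input shape and the result is deterministic for a
    fixed checkpoint.  ``ckpt`` may be a :class:`Checkpoint`, a path to one,
    or any object exposing ``predict(array) -> array`` plus ``norm_mean`` /
    ``norm_std`` attributes (used by plumbing tests).
    """
    if isinstance(ckpt, (str, Path)):
        ckpt = load_checkpoint(ckpt)
    if isinstance(ckpt, Checkpoint):
        model = ckpt.build_model()
        mean, std = ckpt.norm_mean, ckpt.norm_std
        min_t = model.cfg.min_frames
    else:  # duck-typed model (plumbing/tests)
        model = ckpt
        mean = getattr(ckpt, "norm_mean", 0.0)
        std = getattr(ckpt, "norm_std", 1.0)
        min_t = 1

    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack, dtype=np.float32)
    H, W, T = data.shape
    if T < min_t:
        raise ValueError(
            f"stack has only {T} frames; the model needs at least {min_t} — "
            "denoise a longer acquisition or reduce the temporal compression"
        )
    th, tw, tt = (min(t, s) for t, s in zip(tiles.tile_shape, (H, W, T)))
    oh, ow, ot = (min(o, t - 1) for o, t in zip(tiles.overlap, (th, tw, tt)))
    oh, ow, ot = (o - o % 2 for o in (oh, ow, ot))
    normed = (data - mean) / std

    out = np.zeros_like(normed, dtype=np.float32)
    filled = np.zeros(normed.shape, dtype=bool)
    for r0 in _tile_starts(H, th, oh):
        for c0 in _tile_starts(W, tw, ow):
            for f0 in _tile_starts(T, tt, ot):
                tile = normed[r0 : r0 + th, c0 : c0 + tw, f0 : f0 + tt]
                pred = np.asarray(model.predict(tile), dtype=np.float32)
                if pred.shape != tile.shape:
                    raise ValueError(f"model returned shape {pred.shape} for tile {tile.shape}")
                # central crop: keep the core, but extend to the stack border
                rl = 0 if r0 == 0 else oh // 2
                cl = 0 if c0 == 0 else ow // 2
                fl = 0 if f0 == 0 else ot // 2
                rh = th if r0 + th == H else th - oh // 2
                ch = tw if c0 + tw == W else tw - ow // 2
                fh = tt if f0 + tt == T else tt - ot // 2
                out[r0 + rl : r0 + rh, c0 + cl : c0 + ch, f0 + fl : f0 + fh] = pred[rl:rh, cl:ch, fl:fh]
                filled[r0 + rl : r0 + rh, c0 + cl : c0 + ch, f0 + fl : f0 + fh] = True
    if not filled.all():  # core regions tile the stack exactly; this is a guard
        raise RuntimeError("stitching left uncovered voxels; tile/overlap configuration invalid")
    restored = np.clip(out * std + mean, 0, None)  # cameras report nonnegative counts
    if isinstance(stack, ImageStack):
        return stack.with_data(restored)
    return ImageStack(restored)


def reorganize_volumetric(volumes: np.ndarray) -> list[ImageStack]:
    """Split (H, W, Z, T) plane-series data into one xy-t stack per plane.

    Volumetric time-lapse data acquired plane by plane is denoised per plane:
    plane ``k`` maps to stack ``k``.  The inverse is
    :func:`assemble_volumetric`.
    """
    arr = np.asarray(volumes)
    if arr.ndim != 4:
        raise ValueError(f"expected 4-D (row, col, plane, time) data; got ndim={arr.ndim}")
    if arr.shape[2] < 1:
        raise ValueError("plane count must be >= 1")
    return [ImageStack(np.ascontiguousarray(arr[:, :, z, :])) for z in range(arr.shape[2])]


def assemble_volumetric(stacks: list[ImageStack]) -> np.ndarray:
    """Inverse of :func:`reorganize_volumetric` (bit-exact round trip)."""
    if not stacks:
        raise ValueError("no planes to assemble")
    shapes = {s.data.shape for s in stacks}
    if len(shapes) != 1:
        raise ValueError(f"ragged plane series: shapes {sorted(shapes)}")
    return np.stack([s.data for s in stacks], axis=2)
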