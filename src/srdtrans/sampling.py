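"""Spatial-redundancy orthogonal sampling.

A single noisy stack is converted into self-supervised training triplets:
every frame is divided into 2x2 blocks, one of the four pixels of each block
is drawn uniformly as the *center*, and its horizontal and vertical
neighbours inside the same block become the two targets.  Because shot and
read noise are independent between adjacent pixels while the optical signal
is highly correlated, the center substack S_c and each neighbour substack
(S_h, S_v) form a valid noisy-input/noisy-target training pair.

Coordinates are 0-based ``(row, col, frame)``, row-major.  One mask is drawn
per triplet and shared by all frames, preserving the temporal continuity the
transformer's temporal attention consumes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stack import ImageStack

__all__ = [
    "SamplingMask",
    "SamplingTriplet",
    "sample_orthogonal_triplet",
    "extract_training_pairs",
    "augment_eightfold",
    "dihedral_inverse",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 42


@dataclass(frozen=True)
class SamplingMask:
    """Per-2x2-block center choice.

    ``center_row_offset[i, j]`` / ``center_col_offset[i, j]`` are 0 or 1 and
    select the center pixel of block ``(i, j)`` at source coordinate
    ``(2i + row_offset, 2j + col_offset)``.  The horizontal neighbour flips
    only the column offset; the vertical neighbour flips only the row offset.
    """

    center_row_offset: np.ndarray
    center_col_offset: np.ndarray

    @property
    def block_grid_shape(self) -> tuple[int, int]:
        return self.center_row_offset.shape  # type: ignore[return-value]

    def center_coords(self) -> tuple[np.ndarray, np.ndarray]:
        nb_r, nb_c = self.block_grid_shape
        bi, bj = np.meshgrid(np.arange(nb_r), np.arange(nb_c), indexing="ij")
        return 2 * bi + self.center_row_offset, 2 * bj + self.center_col_offset

    def horizontal_coords(self) -> tuple[np.ndarray, np.ndarray]:
        r, c = self.center_coords()
        nb_c = self.block_grid_shape[1]
        bj = np.arange(nb_c)[None, :]
        return r, 2 * bj + (1 - self.center_col_offset)

    def vertical_coords(self) -> tuple[np.ndarray, np.ndarray]:
        r, c = self.center_coords()
        nb_r = self.block_grid_shape[0]
        bi = np.arange(nb_r)[:, None]
        return 2 * bi + (1 - self.center_row_offset), c


@dataclass
class SamplingTriplet:
    """Input substack S_c plus its two orthogonal targets S_h, S_v.

    All three have shape ``(H/2, W/2, T)`` and every value is a pure gather
    from the source stack at the coordinate recorded in ``mask``.
    """

    s_c: np.ndarray
    s_h: np.ndarray
    s_v: np.ndarray
    mask: SamplingMask

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.s_c.shape  # type: ignore[return-value]


def _draw_mask(nb_r: int, nb_c: int, rng: np.random.Generator) -> SamplingMask:
    # center uniform over the 4 block positions: two independent fair bits
    return SamplingMask(
        center_row_offset=rng.integers(0, 2, size=(nb_r, nb_c)),
        center_col_offset=rng.integers(0, 2, size=(nb_r, nb_c)),
    )


def _gather(data: np.ndarray, coords: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    r, c = coords
    return data[r, c, :]


def sample_orthogonal_triplet(
    stack: ImageStack | np.ndarray, seed: int | np.random.Generator = DEFAULT_SEED
) -> SamplingTriplet:
    """Draw one orthogonal sampling mask and gather the (S_c, S_h, S_v) triplet.

    The mask is drawn once per call and applied identically to all frames.
    The same seed always reproduces the same triplet bit-for-bit.
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    if data.ndim != 3:
        raise ValueError("expected a 3-D (row, col, frame) array")
    H, W, T = data.shape
    if H % 2:
        raise ValueError(f"row count must be even for 2x2 block sampling; got H={H} (crop first)")
    if W % 2:
        raise ValueError(f"column count must be even for 2x2 block sampling; got W={W} (crop first)")
    if T == 0:
        raise ValueError("empty stack: T must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    mask = _draw_mask(H // 2, W // 2, rng)
    return SamplingTriplet(
        s_c=_gather(data, mask.center_coords()),
        s_h=_gather(data, mask.horizontal_coords()),
        s_v=_gather(data, mask.vertical_coords()),
        mask=mask,
    )


def extract_training_pairs(
    stacks: list[ImageStack] | list[np.ndarray] | ImageStack,
    n_pairs: int = 6000,
    patch_shape: tuple[int, int, int] = (128, 128, 128),
    seed: int = DEFAULT_SEED,
) -> list[SamplingTriplet]:
    """Cut ``n_pairs`` random 3-D patches out of the stacks and sample each.

    Patch origins are drawn uniformly with replacement over all valid
    positions across all stacks (stacks are even-cropped first).  Each
    returned triplet has shape ``(h/2, w/2, t)``.
    """
    if isinstance(stacks, (ImageStack, np.ndarray)):
        stacks = [stacks]  # type: ignore[list-item]
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    h, w, t = patch_shape
    if h % 2 or w % 2:
        raise ValueError(f"patch height/width must be even; got {h}x{w}")
    arrays = []
    for s in stacks:
        a = s.data if isinstance(s, ImageStack) else np.asarray(s)
        a = a[: a.shape[0] - a.shape[0] % 2, : a.shape[1] - a.shape[1] % 2, :]
        arrays.append(a)
    valid = [a for a in arrays if a.shape[0] >= h and a.shape[1] >= w and a.shape[2] >= t]
    if not valid:
        shapes = [a.shape for a in arrays]
        raise ValueError(f"patch {patch_shape} does not fit in any stack; stack shapes {shapes}")
    rng = np.random.default_rng(seed)
    triplets = []
    for _ in range(n_pairs):
        a = valid[int(rng.integers(len(valid)))]
        # even row/col origins keep the 2x2 block lattice aligned with the patch
        r0 = 2 * int(rng.integers((a.shape[0] - h) // 2 + 1))
        c0 = 2 * int(rng.integers((a.shape[1] - w) // 2 + 1))
        f0 = int(rng.integers(a.shape[2] - t + 1))
        patch = a[r0 : r0 + h, c0 : c0 + w, f0 : f0 + t]
        triplets.append(sample_orthogonal_triplet(patch, rng))
    return triplets


def _dihedral(a: np.ndarray, k: int) -> np.ndarray:
    """Element k of the dihedral group of the square on the (row, col) axes."""
    rot = np.rot90(a, k % 4, axes=(0, 1))
    return rot if k < 4 else np.flip(rot, axis=1)


def dihedral_inverse(k: int) -> int:
    """Index of the inverse group element for :func:`augment_eightfold`."""
    if k < 4:
        return (4 - k) % 4
    return k  # rotation-then-flip elements are reflections, hence involutions


def augment_eightfold(triplet: SamplingTriplet, k: int) -> SamplingTriplet:
    """Apply element ``k`` (0..7) of the square's dihedral group in-plane.

    k = 0..3 are rotations by 90k degrees; k = 4..7 are those rotations
    followed by a horizontal flip.  k = 0 is the identity and the frame axis
    is untouched.  All three substacks are transformed identically.
    """
    if not (0 <= int(k) <= 7):
        raise ValueError(f"augmentation index must be in 0..7; got {k}")
    k = int(k)
    return SamplingTriplet(
        s_c=_dihedral(triplet.s_c, k).copy(),
        s_h=_dihedral(triplet.s_h, k).copy(),
        s_v=_dihedral(triplet.s_v, k).copy(),
        mask=triplet.mask,
    )
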