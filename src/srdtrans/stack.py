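"""Image stacks: the universal currency of the pipeline.

An :class:`ImageStack` is a 3-D array of nonnegative intensities indexed
``(row, col, frame)`` — i.e. an *xy–t* time-lapse — with optional physical
metadata (pixel size, frame rate).  Stacks are read from and written to
plain multi-page TIFF files where page order defines time.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import tifffile

__all__ = ["ImageStack", "read_tiff_stack", "write_tiff_stack"]


@dataclass
class ImageStack:
    """A time-lapse intensity stack indexed ``(row, col, frame)``.

    Parameters
    ----------
    data:
        3-D array, shape ``(H, W, T)``.  Cast to float32/float64 on ingest;
        values must be finite and nonnegative.
    pixel_size:
        Physical edge length of one pixel.  Units are carried in
        ``pixel_size_unit`` (``"um"`` or ``"nm"``).
    frame_rate:
        Acquisition rate in Hz.
    """

    data: np.ndarray
    pixel_size: float | None = None
    pixel_size_unit: str = "um"
    frame_rate: float | None = None
    source_dtype: np.dtype | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"stack data must be 3-D (row, col, frame); got ndim={arr.ndim}")
        if self.source_dtype is None:
            self.source_dtype = arr.dtype
        if not np.issubdtype(arr.dtype, np.floating):
            arr = arr.astype(np.float32)
        if not np.all(np.isfinite(arr)):
            raise ValueError("stack contains non-finite values")
        if arr.min() < 0:
            raise ValueError("stack contains negative intensities")
        H, W, T = arr.shape
        if H < 2 or W < 2:
            raise ValueError(f"stack spatial extent must be at least 2x2; got {H}x{W}")
        if T < 1:
            raise ValueError("stack must contain at least one frame")
        self.data = arr

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]

    def with_data(self, data: np.ndarray) -> "ImageStack":
        """Same metadata, new pixel values."""
        return replace(self, data=data)

    def crop_even(self) -> "ImageStack":
        """Drop a trailing row/column so H and W are even (never pads)."""
        H, W, _ = self.shape
        return self.with_data(self.data[: H - H % 2, : W - W % 2, :])


def read_tiff_stack(path: str | Path) -> ImageStack:
    """Read a multi-page TIFF as an ImageStack (page index = frame index).

    Accepts 8/16-bit unsigned or 32/64-bit float pages; values are cast to
    working float and the original dtype is kept in ``source_dtype``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such TIFF file: {path}")
    try:
        pages = tifffile.imread(str(path))
    except Exception as exc:  # tifffile raises several internal types
        raise ValueError(f"not a readable TIFF file: {path} ({exc})") from exc
    arr = np.asarray(pages)
    if arr.ndim == 2:  # single page -> T = 1
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError(f"TIFF {path} has unsupported page layout with ndim={arr.ndim}")
    src = arr.dtype
    # pages are (T, H, W); internal layout is (H, W, T)
    data = np.moveaxis(arr, 0, -1).astype(np.float32)
    return ImageStack(data=data, source_dtype=src)


def write_tiff_stack(stack: ImageStack | np.ndarray, path: str | Path, as_uint16: bool = False) -> None:
    """Write a stack as a multi-page TIFF (frame k -> page k).

    Float32 output by default; ``as_uint16`` rescales to the full 16-bit
    range using the stack min/max.
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    pages = np.moveaxis(data, -1, 0)
    if as_uint16:
        lo, hi = float(pages.min()), float(pages.max())
        scale = 65535.0 / (hi - lo) if hi > lo else 1.0
        pages = np.clip((pages - lo) * scale, 0, 65535).astype(np.uint16)
    else:
        pages = pages.astype(np.float32)
    tifffile.imwrite(str(path), pages)
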