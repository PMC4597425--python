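"""8-bit grayscale TIFF input/output and the zero-padded embedding geometry.

Working images are 2-D float arrays on the nominal [0, 255] scale; values are
quantized to 8-bit integers only at file boundaries, so the spectral filter
never accumulates rounding error.  Rectangular images are centered in an even
square array of zeros before spectral smoothing and cropped back afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import tifffile

__all__ = [
    "EmbedRecord",
    "quantize",
    "read_gray_tiff",
    "write_gray_tiff",
    "invert",
    "embed_center",
    "crop_center",
]


@dataclass(frozen=True)
class EmbedRecord:
    """Geometry of a centered zero-padded embedding.

    The inner image's top-left corner sits at ``(offset_row, offset_col)``
    inside an ``outer_side`` x ``outer_side`` square; offsets are the floored
    centered values ``(outer - inner) // 2``.
    """

    inner_height: int
    inner_width: int
    offset_row: int
    offset_col: int
    outer_side: int

    def __post_init__(self) -> None:
        if self.offset_row + self.inner_height > self.outer_side:
            raise ValueError("embed record rows exceed outer side")
        if self.offset_col + self.inner_width > self.outer_side:
            raise ValueError("embed record columns exceed outer side")

    def to_dict(self) -> dict:
        return {
            "inner_height": self.inner_height,
            "inner_width": self.inner_width,
            "offset_row": self.offset_row,
            "offset_col": self.offset_col,
            "outer_side": self.outer_side,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EmbedRecord":
        return cls(
            inner_height=int(d["inner_height"]),
            inner_width=int(d["inner_width"]),
            offset_row=int(d["offset_row"]),
            offset_col=int(d["offset_col"]),
            outer_side=int(d["outer_side"]),
        )


def _as_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError(f"expected a 2-D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    return arr


def quantize(image: np.ndarray) -> np.ndarray:
    """Clip to [0, 255] and round half away from zero, returning uint8.

    This single rounding rule is shared by every file/display boundary in the
    package so that replays are byte-exact.
    """
    arr = _as_image(image)
    clipped = np.clip(arr, 0.0, 255.0)
    # all values nonnegative after the clip, so half-away-from-zero == floor(x+0.5)
    return np.floor(clipped + 0.5).astype(np.uint8)


def read_gray_tiff(path) -> np.ndarray:
    """Read a single-channel 8-bit grayscale TIFF as a float image in [0, 255].

    Multi-channel files whose channels are identical are collapsed to one
    channel; anything else (16-bit, float, genuine color) is rejected with a
    message naming the offending property.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    arr = tifffile.imread(path)
    if arr.dtype != np.uint8:
        raise ValueError(
            f"{path}: expected 8-bit grayscale TIFF, got bit depth "
            f"{arr.dtype.itemsize * 8} ({arr.dtype})"
        )
    if arr.ndim == 3:
        if np.all(arr == arr[..., :1]):
            arr = arr[..., 0]
        else:
            raise ValueError(
                f"{path}: expected grayscale TIFF, got {arr.shape[-1]}-channel "
                "color image with distinct channels"
            )
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    return arr.astype(float)


def write_gray_tiff(image: np.ndarray, path) -> None:
    """Quantize and write as uncompressed single-strip 8-bit grayscale TIFF."""
    data = quantize(image)
    tifffile.imwrite(
        Path(path),
        data,
        photometric="minisblack",
        compression=None,
        rowsperstrip=data.shape[0],
    )


def invert(image: np.ndarray) -> np.ndarray:
    """Intensity reversal v -> 255 - v on the nominal scale.

    Swaps white-ridge and black-ridge polarity; an involution.
    """
    arr = _as_image(image)
    if arr.min() < 0 or arr.max() > 255:
        raise ValueError(
            "invert is defined on the nominal [0, 255] scale; "
            f"got values in [{arr.min():g}, {arr.max():g}]"
        )
    return 255.0 - arr


def embed_center(image: np.ndarray, outer_side: int) -> tuple[np.ndarray, EmbedRecord]:
    """Center ``image`` in an ``outer_side`` square of zeros.

    ``outer_side`` must be even (the spectral grid wants even dimensions) and
    at least as large as both image dimensions.  Offsets use floor division.
    Returns the padded square and the :class:`EmbedRecord` needed to crop back.
    """
    arr = _as_image(image)
    h, w = arr.shape
    outer_side = int(outer_side)
    if outer_side % 2 != 0:
        raise ValueError(f"outer_side must be even, got {outer_side}")
    if outer_side < max(h, w):
        raise ValueError(
            f"outer_side {outer_side} too small; must be >= max(height, width) = {max(h, w)}"
        )
    off_r = (outer_side - h) // 2
    off_c = (outer_side - w) // 2
    out = np.zeros((outer_side, outer_side), dtype=float)
    out[off_r : off_r + h, off_c : off_c + w] = arr
    record = EmbedRecord(
        inner_height=h,
        inner_width=w,
        offset_row=off_r,
        offset_col=off_c,
        outer_side=outer_side,
    )
    return out, record


def crop_center(image: np.ndarray, record: EmbedRecord) -> np.ndarray:
    """Recover the inner window recorded by :func:`embed_center`."""
    arr = _as_image(image)
    if arr.shape != (record.outer_side, record.outer_side):
        raise ValueError(
            f"image shape {arr.shape} inconsistent with embed record "
            f"outer side {record.outer_side}"
        )
    r, c = record.offset_row, record.offset_col
    return arr[r : r + record.inner_height, c : c + record.inner_width].copy()
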