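"""Global and tile-based adaptive histogram equalization for 8-bit images.

Both operations use the min-shift equalization variant: with ``cdf`` the
cumulative intensity distribution and ``cdf_min`` its value at the smallest
occupied bin, a value v maps to ``round(255 * (cdf(v) - cdf_min) / (1 - cdf_min))``,
so the darkest occupied level maps to 0 and the full output range is used.
Adaptive equalization computes that mapping per tile (optionally with
histogram clipping) and applies it with bilinear interpolation between the
four surrounding tile-center mappings, which avoids seam artifacts that a
blockwise application would cut through ridge structure.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .raster_io import quantize

__all__ = [
    "HistogramTable",
    "compute_histogram",
    "equalize_global",
    "equalize_adaptive",
]


@dataclass(frozen=True)
class HistogramTable:
    """Per-level pixel counts and the normalized cumulative distribution."""

    counts: np.ndarray  # 256 non-negative ints
    cdf: np.ndarray  # 256 reals, non-decreasing, last value 1


def _require_quantized(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image)
    if arr.dtype == np.uint8:
        return arr
    farr = np.asarray(arr, dtype=float)
    if (
        not np.all(np.isfinite(farr))
        or np.any(farr != np.floor(farr))
        or farr.min() < 0
        or farr.max() > 255
    ):
        raise ValueError(
            "expected a quantized image (integers in [0, 255]); "
            "quantize() the image first"
        )
    return farr.astype(np.uint8)


def compute_histogram(image: np.ndarray) -> HistogramTable:
    """Histogram of a quantized image over the 256 gray levels."""
    arr = _require_quantized(image)
    counts = np.bincount(arr.ravel(), minlength=256)
    cdf = np.cumsum(counts) / arr.size
    return HistogramTable(counts=counts, cdf=cdf)


def _equalization_lut(counts: np.ndarray) -> np.ndarray | None:
    """256-entry lookup table for min-shift equalization; None if degenerate.

    Degenerate means fewer than two occupied bins, where the mapping is
    undefined and callers fall back to identity.
    """
    occupied = np.nonzero(counts)[0]
    if occupied.size < 2:
        return None
    total = counts.sum()
    cdf = np.cumsum(counts) / total
    cdf_min = cdf[occupied[0]]
    scaled = 255.0 * (cdf - cdf_min) / (1.0 - cdf_min)
    return np.floor(np.clip(scaled, 0.0, 255.0) + 0.5).astype(np.uint8)


def equalize_global(image: np.ndarray) -> np.ndarray:
    """Whole-image histogram equalization of a quantized image.

    The value mapping is monotone non-decreasing, so pixel ranking is
    preserved.  A constant image is returned unchanged with a warning: the
    mapping is undefined there.
    """
    arr = _require_quantized(image)
    table = compute_histogram(arr)
    lut = _equalization_lut(table.counts)
    if lut is None:
        warnings.warn(
            "equalize_global: image has fewer than two distinct values; "
            "mapping undefined, returning input unchanged",
            stacklevel=2,
        )
        return arr.astype(float)
    return lut[arr].astype(float)


def _clip_histogram(counts: np.ndarray, clip_limit: float) -> np.ndarray:
    """Clip counts at clip_limit x uniform height, redistributing the excess
    uniformly over all 256 bins (one pass; standard contrast limiting)."""
    total = counts.sum()
    ceiling = clip_limit * total / 256.0
    clipped = np.minimum(counts.astype(float), ceiling)
    excess = total - clipped.sum()
    return clipped + excess / 256.0


def _tile_edges(length: int, tiles: int) -> np.ndarray:
    """Boundaries partitioning ``length`` pixels into ``tiles`` near-equal tiles."""
    return np.round(np.linspace(0, length, tiles + 1)).astype(int)


def equalize_adaptive(
    image: np.ndarray,
    tiles_y: int = 8,
    tiles_x: int = 8,
    clip_limit: float | None = None,
) -> np.ndarray:
    """Tile-based adaptive histogram equalization with bilinear blending.

    The image is partitioned into ``tiles_y`` x ``tiles_x`` tiles; each tile
    gets its own min-shift equalization lookup table (histogram-clipped at
    ``clip_limit`` x the uniform bin height when a clip limit is given).  Each
    pixel's output interpolates the four surrounding tile-center mappings;
    border pixels use the nearest available tiles.  With a single tile this
    reduces exactly to :func:`equalize_global`.
    """
    arr = _require_quantized(image)
    h, w = arr.shape
    tiles_y, tiles_x = int(tiles_y), int(tiles_x)
    if tiles_y < 1 or tiles_x < 1:
        raise ValueError("tile counts must be >= 1")
    if h < 2 * tiles_y or w < 2 * tiles_x:
        raise ValueError(
            f"image {h}x{w} too small for a {tiles_y}x{tiles_x} tile grid; "
            f"needs at least {2 * tiles_y}x{2 * tiles_x} (2 px per tile)"
        )

    edges_y = _tile_edges(h, tiles_y)
    edges_x = _tile_edges(w, tiles_x)

    identity = np.arange(256, dtype=np.uint8)
    luts = np.empty((tiles_y, tiles_x, 256), dtype=np.uint8)
    any_defined = False
    for ty in range(tiles_y):
        for tx in range(tiles_x):
            tile = arr[edges_y[ty] : edges_y[ty + 1], edges_x[tx] : edges_x[tx + 1]]
            counts = np.bincount(tile.ravel(), minlength=256).astype(float)
            if clip_limit is not None:
                counts = _clip_histogram(counts, float(clip_limit))
            lut = _equalization_lut(counts)
            if lut is None:
                luts[ty, tx] = identity
            else:
                luts[ty, tx] = lut
                any_defined = True

    if not any_defined:
        warnings.warn(
            "equalize_adaptive: all tile mappings undefined (constant tiles); "
            "returning input unchanged",
            stacklevel=2,
        )
        return arr.astype(float)

    centers_y = (edges_y[:-1] + edges_y[1:] - 1) / 2.0
    centers_x = (edges_x[:-1] + edges_x[1:] - 1) / 2.0

    def _axis_weights(n: int, centers: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # bracketing tile indices and the blend weight toward the upper tile;
        # coordinates beyond the first/last center clamp to the nearest tile
        coords = np.arange(n, dtype=float)
        hi = np.searchsorted(centers, coords)
        lo = np.clip(hi - 1, 0, len(centers) - 1)
        hi = np.clip(hi, 0, len(centers) - 1)
        span = centers[hi] - centers[lo]
        with np.errstate(invalid="ignore", divide="ignore"):
            wt = np.where(span > 0, (coords - centers[lo]) / np.where(span > 0, span, 1.0), 0.0)
        return lo, hi, np.clip(wt, 0.0, 1.0)

    lo_y, hi_y, wy = _axis_weights(h, centers_y)
    lo_x, hi_x, wx = _axis_weights(w, centers_x)

    wy = wy[:, None]
    wx = wx[None, :]
    out = np.zeros((h, w), dtype=float)
    for yi, ywt in ((lo_y, 1.0 - wy), (hi_y, wy)):
        for xi, xwt in ((lo_x, 1.0 - wx), (hi_x, wx)):
            mapped = luts[yi[:, None], xi[None, :], arr]
            out += ywt * xwt * mapped
    return quantize(out).astype(float)
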