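"""Synthetic latent-print-like fixtures.

Real latent prints are low-contrast friction-ridge impressions buried in
clutter: streaks, text-like marks, illumination gradients and noise, and
they come from non-public forensic collections.  This module emulates those
features so every pipeline stage is testable: a smoothly varying orientation
field drives an oriented stripe (ridge) pattern, masked to an elliptical
print region, composited over a cluttered background.  The clean masked
ridge term is returned alongside the latent as ground truth, so fidelity
metrics need no registration step.

All randomness flows from the single ``seed`` through one named generator;
fixtures are bit-reproducible.  This is deliberately *not* a physically
realistic fingerprint simulator — no minutiae, pores or elastic distortion —
just the oriented-texture-in-clutter structure the smoothing stage must cope
with.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster_io import quantize

__all__ = [
    "SyntheticPrintParams",
    "orientation_field",
    "ridge_pattern",
    "generate_latent",
    "print_mask",
    "masked_correlation",
]


@dataclass(frozen=True)
class SyntheticPrintParams:
    """Conditions for one synthetic latent print.

    Gray-level magnitudes are on the nominal [0, 255] scale; ``ridge_period``
    is pixels per ridge cycle and ``orientation_scale`` the distance over
    which ridge orientation drifts appreciably.
    """

    height: int = 480
    width: int = 640
    ridge_period: float = 10.0
    orientation_scale: float = 200.0
    ridge_contrast: float = 60.0
    background_level: float = 120.0
    gradient_amplitude: float = 25.0
    noise_sigma: float = 15.0
    n_streaks: int = 4
    text_blocks: int = 1
    smudge_radius: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ridge_period < 4:
            raise ValueError("ridge_period must be >= 4 pixels per cycle")
        if self.height < 1 or self.width < 1:
            raise ValueError("image dimensions must be >= 1")


def orientation_field(
    height: int, width: int, orientation_scale: float, seed: int
) -> np.ndarray:
    """Smooth random ridge-orientation field in radians.

    Random angles are drawn on a coarse grid with one node per
    ``orientation_scale`` pixels and upsampled with bilinear interpolation,
    which bounds the per-pixel angle gradient by pi / orientation_scale
    (coarse nodes span at most pi).
    """
    rng = np.random.default_rng(seed)
    ny = max(1, int(np.ceil(height / orientation_scale)))
    nx = max(1, int(np.ceil(width / orientation_scale)))
    coarse = rng.uniform(-np.pi / 2, np.pi / 2, size=(ny + 1, nx + 1))
    if orientation_scale >= max(height, width):
        # degenerate 1x1 coarse grid: constant field
        return np.full((height, width), coarse[0, 0])
    # nodes sit orientation_scale pixels apart, so the bilinear surface's
    # per-pixel gradient never exceeds (coarse span pi) / orientation_scale
    rows = np.arange(height) / orientation_scale
    cols = np.arange(width) / orientation_scale
    r0 = np.clip(rows.astype(int), 0, ny - 1)
    c0 = np.clip(cols.astype(int), 0, nx - 1)
    fr = (rows - r0)[:, None]
    fc = (cols - c0)[None, :]
    a = coarse[np.ix_(r0, c0)]
    b = coarse[np.ix_(r0, c0 + 1)]
    c = coarse[np.ix_(r0 + 1, c0)]
    d = coarse[np.ix_(r0 + 1, c0 + 1)]
    return (1 - fr) * ((1 - fc) * a + fc * b) + fr * ((1 - fc) * c + fc * d)


def ridge_pattern(
    height: int, width: int, ridge_period: float, field: np.ndarray
) -> np.ndarray:
    """Oriented stripe pattern cos(2*pi*phi) with values in [-1, 1].

    The phase phi integrates the local wave vector
    (cos(theta), sin(theta)) / ridge_period along the image axes (columns
    within each row, rows along the first column), which keeps the phase
    continuous instead of tearing where orientation drifts.  A constant field
    theta = 0 gives vertical stripes of exact period ``ridge_period``.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != (height, width):
        raise ValueError(
            f"orientation field shape {field.shape} does not match {height}x{width}"
        )
    kx = np.cos(field) / ridge_period
    ky = np.sin(field) / ridge_period
    phase = np.cumsum(kx, axis=1)
    phase += np.cumsum(ky[:, 0])[:, None]
    return np.cos(2 * np.pi * phase)


def _ellipse_mask(height: int, width: int, rng: np.random.Generator) -> np.ndarray:
    """Elliptical print-region mask with mild seeded center jitter."""
    cy = height / 2 + rng.uniform(-0.03, 0.03) * height
    cx = width / 2 + rng.uniform(-0.03, 0.03) * width
    ay = 0.40 * height
    ax = 0.38 * width
    yy = np.arange(height)[:, None]
    xx = np.arange(width)[None, :]
    return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0


def _streaks(
    height: int, width: int, n_streaks: int, rng: np.random.Generator
) -> np.ndarray:
    """Bright line segments crossing the frame, 2-3 px wide, ~40 gray levels."""
    out = np.zeros((height, width))
    yy = np.arange(height)[:, None]
    xx = np.arange(width)[None, :]
    for _ in range(n_streaks):
        theta = rng.uniform(0, np.pi)
        # signed distance from a line through a random interior point
        py = rng.uniform(0.1, 0.9) * height
        px = rng.uniform(0.1, 0.9) * width
        dist = np.abs((yy - py) * np.cos(theta) - (xx - px) * np.sin(theta))
        half_width = rng.uniform(1.0, 1.5)
        amplitude = rng.uniform(30.0, 50.0)
        out += amplitude * np.exp(-0.5 * (dist / half_width) ** 2)
    return out


def _text_marks(
    height: int, width: int, text_blocks: int, rng: np.random.Generator
) -> np.ndarray:
    """Text-like clutter: rows of short bright bars inside small rectangles."""
    out = np.zeros((height, width))
    for _ in range(text_blocks):
        bh = int(rng.uniform(0.03, 0.06) * height) + 4
        bw = int(rng.uniform(0.15, 0.35) * width) + 8
        r0 = rng.integers(0, max(1, height - bh))
        c0 = rng.integers(0, max(1, width - bw))
        amplitude = rng.uniform(50.0, 80.0)
        c = c0
        while c < c0 + bw - 2:
            glyph_w = int(rng.integers(2, 6))
            gap = int(rng.integers(1, 4))
            if rng.uniform() < 0.75:
                out[r0 : r0 + bh, c : min(c + glyph_w, width)] += amplitude
            c += glyph_w + gap
    return out


def _illumination_gradient(
    height: int, width: int, amplitude: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth low-order illumination drift, ~plus/minus ``amplitude`` levels."""
    yy = np.linspace(-1, 1, height)[:, None]
    xx = np.linspace(-1, 1, width)[None, :]
    gy, gx, gq = rng.uniform(-amplitude, amplitude, size=3)
    return gy * yy + gx * xx + gq * (yy * xx)


def generate_latent(params: SyntheticPrintParams) -> tuple[np.ndarray, np.ndarray]:
    """Build a cluttered synthetic latent print and its ridge ground truth.

    Returns ``(latent, clean_ridges)``: the latent is the quantized composite
    background + illumination gradient + masked bright ridges + streaks +
    text marks + Gaussian noise (+ optional disk-kernel smudge blur);
    ``clean_ridges`` is the unclipped masked ridge term alone.  Fully
    determined by ``params.seed``.
    """
    h, w = params.height, params.width
    rng = np.random.default_rng(params.seed)
    # fixed draw order: field seed, ellipse, gradient, streaks, text, noise
    field_seed = int(rng.integers(0, 2**31 - 1))
    field = orientation_field(h, w, params.orientation_scale, field_seed)
    ridges = ridge_pattern(h, w, params.ridge_period, field)
    mask = _ellipse_mask(h, w, rng)
    clean = (params.ridge_contrast / 2.0) * ridges * mask
    gradient = _illumination_gradient(h, w, params.gradient_amplitude, rng)
    streaks = _streaks(h, w, params.n_streaks, rng)
    text = _text_marks(h, w, params.text_blocks, rng)
    noise = rng.normal(0.0, params.noise_sigma, size=(h, w)) if params.noise_sigma > 0 else 0.0
    latent = params.background_level + gradient + clean + streaks + text + noise
    if params.smudge_radius > 0:
        r = int(np.ceil(params.smudge_radius))
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        disk = (yy**2 + xx**2 <= params.smudge_radius**2).astype(float)
        latent = ndimage.convolve(latent, disk / disk.sum(), mode="reflect")
    return quantize(latent).astype(float), clean


def print_mask(params: SyntheticPrintParams) -> np.ndarray:
    """The elliptical print-region mask used by :func:`generate_latent`.

    Recomputed from the same seeded draw order, so it matches the fixture
    exactly without being a third return value.
    """
    rng = np.random.default_rng(params.seed)
    rng.integers(0, 2**31 - 1)  # consume the orientation-field seed draw
    return _ellipse_mask(params.height, params.width, rng)


def masked_correlation(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Pearson correlation of two images restricted to a boolean mask."""
    x = np.asarray(a, dtype=float)[mask]
    y = np.asarray(b, dtype=float)[mask]
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    if denom == 0:
        return 0.0
    return float((x * y).sum() / denom)
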