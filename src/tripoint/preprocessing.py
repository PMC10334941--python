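"""Dermoscopic image preprocessing: crop/resize, color constancy, CLAHE.

The chain normalizes heterogeneous acquisition conditions before training:

1. ``crop_resize`` — largest centered square crop, then a fixed bilinear
   resample to the target side length (dermoscopic framing keeps the lesion
   near the image center, so a center crop preserves it).
2. Shades-of-Gray color constancy — the scene illuminant is estimated from
   the Minkowski p-mean of each channel and divided out, mapping the image
   to a neutrally lit rendering.  p=1 reduces to Gray World and p→∞ to
   max-RGB; the default p=6 is the canonical compromise.
3. CLAHE — contrast-limited adaptive histogram equalization, applied to the
   CIELAB lightness channel only so local contrast is enhanced without
   distorting hue.

All stages operate on floating-point intensities in [0, 1]; quantization to
8 bits happens only when an image is written to disk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import color as _skcolor
from skimage import exposure as _skexposure
from skimage import transform as _sktransform

__all__ = [
    "LesionImage",
    "PreprocessConfig",
    "crop_resize",
    "estimate_illuminant",
    "apply_illuminant",
    "shades_of_gray",
    "clahe",
    "preprocess_image",
]

_STAGES = ("crop_resize", "color_constancy", "clahe")


@dataclass
class LesionImage:
    """An RGB lesion raster: H×W×3 float intensities in [0, 1] plus an id."""

    pixels: np.ndarray
    image_id: str = ""
    color_space: str = "RGB"

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError(f"expected H×W×3 pixels, got shape {px.shape}")
        if px.size and (px.min() < -1e-9 or px.max() > 1.0 + 1e-9):
            raise ValueError("intensities must lie in [0, 1]")
        self.pixels = np.clip(px, 0.0, 1.0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass
class PreprocessConfig:
    target_size: int = 64
    minkowski_p: float = 6.0
    clahe_clip_limit: float = 0.01
    clahe_tile_grid: tuple[int, int] = (8, 8)
    enabled_stages: tuple[str, ...] = _STAGES

    def __post_init__(self) -> None:
        if self.target_size <= 0:
            raise ValueError("target_size must be positive")
        if self.minkowski_p < 1:
            raise ValueError("minkowski_p must be >= 1")
        if self.clahe_clip_limit <= 0:
            raise ValueError("clahe_clip_limit must be positive")
        unknown = set(self.enabled_stages) - set(_STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {_STAGES}")


def crop_resize(image: LesionImage, target_size: int) -> LesionImage:
    """Largest centered square crop followed by a bilinear resample."""
    h, w = image.shape
    if h < 2 or w < 2:
        raise ValueError(f"image too small to crop: {h}×{w}")
    side = min(h, w)
    top = (h - side) // 2
    left = (w - side) // 2
    crop = image.pixels[top : top + side, left : left + side]
    if side == target_size:
        return LesionImage(crop.copy(), image.image_id)
    out = _sktransform.resize(
        crop,
        (target_size, target_size, 3),
        order=1,
        mode="edge",
        anti_aliasing=side > target_size,
        preserve_range=True,
    )
    return LesionImage(np.clip(out, 0.0, 1.0), image.image_id)


def _minkowski_means(pixels: np.ndarray, p: float) -> np.ndarray:
    flat = pixels.reshape(-1, 3).astype(np.float64)
    return (flat**p).mean(axis=0) ** (1.0 / p)


def estimate_illuminant(image: LesionImage, p: float = 6.0) -> np.ndarray:
    """Shades-of-Gray illuminant estimate, returned as per-channel gains.

    The illuminant direction is the per-channel Minkowski p-mean of the
    intensities (normalized to unit norm); the gains map it to neutral gray
    while preserving overall brightness, i.e. gain_c = m̄ / m_c with m̄ the
    arithmetic mean of the three channel p-means.
    """
    if p < 1:
        raise ValueError("Minkowski exponent p must be >= 1")
    m = _minkowski_means(image.pixels, p)
    if np.any(m == 0):
        raise ValueError("illuminant undefined: a channel is identically zero")
    return m.mean() / m


def apply_illuminant(image: LesionImage, gains: np.ndarray) -> LesionImage:
    """Multiply each channel by its gain and clip to the valid range."""
    g = np.asarray(gains, dtype=np.float64)
    if g.shape != (3,) or np.any(g <= 0):
        raise ValueError("gains must be three positive numbers")
    out = np.clip(image.pixels * g[None, None, :], 0.0, 1.0)
    return LesionImage(out, image.image_id)


def shades_of_gray(image: LesionImage, p: float = 6.0) -> LesionImage:
    """Estimate and divide out the illuminant in one step."""
    return apply_illuminant(image, estimate_illuminant(image, p))


def clahe(
    image: LesionImage,
    clip_limit: float = 0.01,
    tile_grid: tuple[int, int] = (8, 8),
) -> LesionImage:
    """Contrast-limited adaptive histogram equalization on lightness.

    The image is converted to CIELAB; L is equalized per tile with a
    clipped histogram (bilinear interpolation between tile mappings) and
    the chroma channels pass through untouched, so hue is preserved up to
    the Lab round-trip.  ``clip_limit`` is the normalized clip fraction in
    (0, 1]; ``tile_grid`` is (rows, cols) of tiles.
    """
    if clip_limit <= 0:
        raise ValueError("clip_limit must be positive")
    gy, gx = int(tile_grid[0]), int(tile_grid[1])
    h, w = image.shape
    if gy < 1 or gx < 1 or gy > h or gx > w:
        raise ValueError(f"tile grid {tile_grid} does not fit a {h}×{w} image")
    lab = _skcolor.rgb2lab(image.pixels)
    lum = lab[:, :, 0] / 100.0
    kernel = (max(1, int(np.ceil(h / gy))), max(1, int(np.ceil(w / gx))))
    if np.ptp(lum) < 1e-12:
        # constant lightness: nothing to equalize, avoid 0-range rescale
        eq = lum
    else:
        eq = _skexposure.equalize_adapthist(
            np.clip(lum, 0.0, 1.0), kernel_size=kernel, clip_limit=min(clip_limit, 1.0)
        )
    lab_out = lab.copy()
    lab_out[:, :, 0] = eq * 100.0
    out = np.clip(_skcolor.lab2rgb(lab_out), 0.0, 1.0)
    return LesionImage(out, image.image_id)


def preprocess_image(image: LesionImage, config: PreprocessConfig) -> LesionImage:
    """Run the enabled stages in their configured order."""
    out = image
    for stage in config.enabled_stages:
        if stage == "crop_resize":
            out = crop_resize(out, config.target_size)
        elif stage == "color_constancy":
            out = shades_of_gray(out, config.minkowski_p)
        elif stage == "clahe":
            out = clahe(out, config.clahe_clip_limit, config.clahe_tile_grid)
        else:  # pragma: no cover - config validation rejects this earlier
            raise ValueError(f"unknown stage {stage!r}")
    return out
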