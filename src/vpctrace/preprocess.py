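"""Printout image cleanup: grid removal, cropping, binarization, resizing.

The red calibration grid is removed by a red-dominance predicate rather
than exact color matching, so anti-aliased or slightly faded grids are
still caught while near-black trace ink is never touched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .render import EcgImage

LUMA_WEIGHTS = (0.299, 0.587, 0.114)
BACKGROUND = 255


@dataclass
class TraceMask:
    """Binary ink mask: foreground (trace) is exactly 255, background 0.

    ``crop_offset`` locates the mask's origin (row, col) inside the image
    it was derived from, so layout coordinates can be mapped onto it.
    """

    pixels: np.ndarray
    crop_offset: tuple = (0, 0)

    def __post_init__(self):
        vals = np.unique(self.pixels)
        if not np.all(np.isin(vals, (0, 255))):
            raise ValueError("TraceMask pixels must be exactly 0 or 255")


@dataclass
class ImageTensor:
    """256 x 512 x 3 array in [0, 1] — the 2-D model input."""

    pixels: np.ndarray

    def __post_init__(self):
        if self.pixels.shape != (256, 512, 3):
            raise ValueError(f"ImageTensor must be 256x512x3, got {self.pixels.shape}")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("ImageTensor values must lie in [0, 1]")


def _as_rgb_array(image) -> np.ndarray:
    if isinstance(image, EcgImage):
        return image.pixels
    arr = np.asarray(image)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    return arr


def remove_grid(image, red_margin: int = 30) -> np.ndarray:
    """Erase the red grid and convert to grayscale.

    A pixel is grid if its red channel exceeds both other channels by more
    than ``red_margin``; such pixels become background white, the rest are
    converted by the standard luma weighting.  Grayscale input passes
    through unchanged (no pixel is red-dominant), which makes the
    operation idempotent.
    """
    rgb = _as_rgb_array(image).astype(np.int16)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise ValueError("remove_grid expects an RGB image")
    r, g, b = rgb[..., 0], rgb[..., 1], rgb[..., 2]
    is_grid = (r - np.maximum(g, b)) > red_margin
    gray = np.round(
        LUMA_WEIGHTS[0] * r + LUMA_WEIGHTS[1] * g + LUMA_WEIGHTS[2] * b
    ).astype(np.uint8)
    gray[is_grid] = BACKGROUND
    if is_grid.all():
        warnings.warn("image is entirely red-dominant; result is all background")
    return gray


def crop_to_signal(gray: np.ndarray, margin_px: int = 0,
                   background_min: int = 250) -> tuple[np.ndarray, tuple]:
    """Tight crop around non-background content, expanded by ``margin_px``.

    Returns the cropped image and the (row, col) offset of its origin in
    the input.  Raises if the image holds no signal content.
    """
    gray = np.asarray(gray)
    content = gray < background_min
    if not content.any():
        raise ValueError("no signal content to crop to")
    rows = np.flatnonzero(content.any(axis=1))
    cols = np.flatnonzero(content.any(axis=0))
    r0 = max(rows[0] - margin_px, 0)
    r1 = min(rows[-1] + margin_px + 1, gray.shape[0])
    c0 = max(cols[0] - margin_px, 0)
    c1 = min(cols[-1] + margin_px + 1, gray.shape[1])
    return gray[r0:r1, c0:c1], (int(r0), int(c0))


def binarize_invert(gray: np.ndarray, ink_threshold: int = 128,
                    crop_offset: tuple = (0, 0)) -> TraceMask:
    """Invert intensities and hard-threshold: ink (dark) becomes 255."""
    gray = np.asarray(gray)
    mask = np.where(gray < ink_threshold, 255, 0).astype(np.uint8)
    return TraceMask(pixels=mask, crop_offset=tuple(crop_offset))


def resize_for_image_model(image) -> ImageTensor:
    """Bilinear resize to the fixed 256 x 512 x 3 input, scaled to [0, 1]."""
    arr = _as_rgb_array(image).astype(float)
    if arr.size == 0:
        raise ValueError("empty image")
    if arr.shape[:2] == (256, 512):
        out = arr
    else:
        out = _sk_resize(arr, (256, 512), order=1, mode="edge",
                         anti_aliasing=False, preserve_range=True)
    out = np.clip(out / 255.0, 0.0, 1.0)
    return ImageTensor(pixels=out)
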