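"""Preprocessing: HU windowing and median denoising.

The detector divides by pixel intensity, so the working image lives on a
strictly positive display scale [1, 256]: Hounsfield values inside the
soft-tissue window map linearly onto it and values outside clamp to the
endpoints.  A square median filter then suppresses noise while keeping the
organ boundaries that the detector looks for.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage

from .io_config import CTSlice

__all__ = [
    "DisplayImage",
    "DISPLAY_MIN",
    "DISPLAY_MAX",
    "apply_window",
    "display_from_raster",
    "median_filter_2d",
    "histogram_seed_mask",
]

DISPLAY_MIN = 1.0
DISPLAY_MAX = 256.0


@dataclass
class DisplayImage:
    """Windowed, display-scaled 2D image on [1, 256] (detector input)."""

    pixels: np.ndarray
    provenance: Optional[CTSlice] = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"DisplayImage.pixels must be 2D, got shape {px.shape}")
        if px.size and px.min() < DISPLAY_MIN:
            raise ValueError(
                f"DisplayImage must be >= {DISPLAY_MIN} everywhere (min {px.min()})"
            )
        self.pixels = px

    @property
    def shape(self):
        return self.pixels.shape


def apply_window(ct: CTSlice, width: float, level: float) -> DisplayImage:
    """Map HU linearly onto the display scale [1, 256], clamping outside.

    HU in ``[level - width/2, level + width/2]`` maps linearly onto
    [1, 256]; the window floor maps to 1 and the ceiling to 256, so the
    window center lands on the display midpoint 128.5.
    """
    if not width > 0:
        raise ValueError(f"window width must be > 0, got {width}")
    lo = level - width / 2.0
    scaled = DISPLAY_MIN + (ct.pixels - lo) * (DISPLAY_MAX - DISPLAY_MIN) / width
    return DisplayImage(np.clip(scaled, DISPLAY_MIN, DISPLAY_MAX), provenance=ct)


def display_from_raster(ct: CTSlice) -> DisplayImage:
    """Wrap an already display-scaled raster slice, clamping into [1, 256]."""
    return DisplayImage(np.clip(ct.pixels, DISPLAY_MIN, DISPLAY_MAX), provenance=ct)


def median_filter_2d(image: DisplayImage, window: int) -> DisplayImage:
    """Square median filter with edge replication at the borders.

    The median of a window never leaves the input's value range, so the
    output stays on [1, 256].
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"median window must be odd and >= 1, got {window}")
    out = ndimage.median_filter(image.pixels, size=window, mode="nearest")
    return DisplayImage(out, provenance=image.provenance)


def histogram_seed_mask(image: DisplayImage) -> np.ndarray:
    """Histogram-mode seed mask (diagnostic only).

    Marks pixels within +/-3 display units of the histogram mode ``p`` — the
    rough liver-intensity band used by histogram-seeded region methods.  The
    detection pipeline itself does not use it: every pixel of the input image
    is evaluated directly (the seed image is the image).  Ties between modes
    resolve to the lowest intensity, with a warning.
    """
    px = image.pixels
    if px.size == 0:
        raise ValueError("image is empty")
    rounded = np.rint(px).astype(np.int64)
    counts = np.bincount(rounded.ravel(), minlength=int(DISPLAY_MAX) + 1)
    top = counts.max()
    modes = np.flatnonzero(counts == top)
    p = int(modes[0])
    if len(modes) > 1:
        warnings.warn(
            f"histogram mode tie at intensities {modes.tolist()}; using lowest ({p})",
            stacklevel=2,
        )
    return ((rounded >= p - 3) & (rounded <= p + 3)).astype(np.uint8)
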