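"""Single-block linear detection: directional ratio parameters.

For every pixel (the "seed"), and for each of the eight principal
directions, a candidate point sits one pixel away along the direction.  Two
N x N blocks flank the candidate at floor(w/2) pixels on either side along
the same axis, and the ratio parameter

    R_c = (C1 + C2 - 2 * V_c) / (2 * V_c)

compares the flanking block means C1, C2 to the candidate intensity V_c.
|R_c| is large when the candidate lies on a dark line or boundary between
brighter structures; the per-pixel maximum of |R_c| over the eight
directions, thresholded at T, yields the binary confidence matrix of edge
evidence.  The ratio is scale-free: multiplying the image by k > 0 changes
nothing.

Diagonal offsets are full-pixel diagonal steps (no interpolation), so all
distances are in Chebyshev pixels.  A border margin of floor(w/2) +
floor(N/2) + 1 pixels, where the geometry would leave the image, is flagged
invalid and treated as non-edge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple, Union

import numpy as np

from .io_config import SBLDAParams
from .preprocess import DisplayImage

__all__ = [
    "RatioField",
    "direction_offset",
    "block_ct_value",
    "ratio_parameter",
    "max_ratio_field",
    "confidence_matrix",
]

ImageLike = Union[DisplayImage, np.ndarray]


def _pixels(image: ImageLike) -> np.ndarray:
    if isinstance(image, DisplayImage):
        return image.pixels
    return np.asarray(image, dtype=np.float64)


def direction_offset(theta: float) -> Tuple[int, int]:
    """Unit grid offset (drow, dcol) for an angle in degrees.

    0 deg points to image right (+col), 90 deg to image top (-row); each
    component is rounded to {-1, 0, 1}, so diagonals are full-pixel steps.
    """
    rad = math.radians(theta)
    dr = -int(round(math.sin(rad)))
    dc = int(round(math.cos(rad)))
    if dr == 0 and dc == 0:
        raise ValueError(f"direction {theta} deg has no grid offset")
    return dr, dc


def _perp(offset: Tuple[int, int]) -> Tuple[int, int]:
    dr, dc = offset
    return -dc, dr


@dataclass
class RatioField:
    """Per-pixel maximal directional ratio magnitude R_m.

    ``values`` is NaN inside the border ``margin`` where the detection
    geometry leaves the image; elsewhere it is the max of |R_c| over the
    direction set (non-negative).
    """

    values: np.ndarray
    margin: int

    @property
    def valid_mask(self) -> np.ndarray:
        return ~np.isnan(self.values)


def block_ct_value(image: ImageLike, center: Tuple[int, int], n: int) -> float:
    """Mean intensity of the N x N block centered at ``center``.

    The sum is accumulated in row-major order and divided by N^2, matching
    the vectorized field computation bit for bit.
    """
    if n < 1 or n % 2 == 0:
        raise ValueError(f"block size N must be odd and >= 1, got {n}")
    px = _pixels(image)
    r, c = int(center[0]), int(center[1])
    h = n // 2
    if r - h < 0 or c - h < 0 or r + h >= px.shape[0] or c + h >= px.shape[1]:
        raise IndexError(f"{n}x{n} block at {center} leaves image of shape {px.shape}")
    total = 0.0
    for i in range(r - h, r + h + 1):
        for j in range(c - h, c + h + 1):
            total += px[i, j]
    return total / (n * n)


def ratio_parameter(
    image: ImageLike,
    seed: Tuple[int, int],
    theta: float,
    w: int,
    n: int,
    perpendicular: bool = False,
) -> float:
    """Directional ratio parameter R_c at one seed pixel.

    The candidate point is one pixel from ``seed`` along ``theta``; the two
    flanking blocks sit floor(w/2) pixels from the candidate along the same
    axis (or at right angles to it when ``perpendicular``).
    """
    if w < 3 or w % 2 == 0:
        raise ValueError(f"detection window w must be odd and >= 3, got {w}")
    px = _pixels(image)
    u = direction_offset(theta)
    axis = _perp(u) if perpendicular else u
    h = w // 2
    r, c = int(seed[0]) + u[0], int(seed[1]) + u[1]
    if not (0 <= r < px.shape[0] and 0 <= c < px.shape[1]):
        raise IndexError(f"candidate point {(r, c)} outside image {px.shape}")
    v = px[r, c]
    c1 = block_ct_value(px, (r + h * axis[0], c + h * axis[1]), n)
    c2 = block_ct_value(px, (r - h * axis[0], c - h * axis[1]), n)
    return (c1 + c2 - 2.0 * v) / (2.0 * v)


def max_ratio_field(image: ImageLike, params: SBLDAParams) -> RatioField:
    """Maximal |R_c| over the direction set, for every interior pixel.

    Vectorized over pixels with shifted array views; the per-pixel
    arithmetic (block-sum accumulation order, then the ratio expression)
    matches the scalar :func:`ratio_parameter` exactly, so results agree
    bit for bit with a per-pixel loop.
    """
    px = _pixels(image)
    hgt, wid = px.shape
    w, n = params.w, params.N
    margin = w // 2 + n // 2 + 1
    if min(hgt, wid) <= 2 * (w + n):
        raise ValueError(
            f"image {px.shape} too small for w={w}, N={n}: need both dims > {2 * (w + n)}"
        )
    padded = np.pad(px, margin, mode="edge")

    def shifted(dr: int, dc: int) -> np.ndarray:
        return padded[margin + dr : margin + dr + hgt, margin + dc : margin + dc + wid]

    half_n = n // 2
    block_cache: dict[Tuple[int, int], np.ndarray] = {}

    def block_mean(dr: int, dc: int) -> np.ndarray:
        key = (dr, dc)
        if key not in block_cache:
            acc = np.zeros((hgt, wid), dtype=np.float64)
            for i in range(-half_n, half_n + 1):
                for j in range(-half_n, half_n + 1):
                    acc += shifted(dr + i, dc + j)
            block_cache[key] = acc / (n * n)
        return block_cache[key]

    h = w // 2
    perpendicular = params.block_orientation == "perpendicular"
    rm = np.zeros((hgt, wid), dtype=np.float64)
    for theta in params.directions:
        u = direction_offset(theta)
        axis = _perp(u) if perpendicular else u
        v = shifted(*u)
        c1 = block_mean(u[0] + h * axis[0], u[1] + h * axis[1])
        c2 = block_mean(u[0] - h * axis[0], u[1] - h * axis[1])
        r = (c1 + c2 - 2.0 * v) / (2.0 * v)
        np.maximum(rm, np.abs(r), out=rm)

    values = np.full((hgt, wid), np.nan)
    values[margin : hgt - margin, margin : wid - margin] = rm[
        margin : hgt - margin, margin : wid - margin
    ]
    return RatioField(values=values, margin=margin)


def confidence_matrix(field: RatioField, t: float) -> np.ndarray:
    """Binary edge-evidence mask: 1 where R_m >= T; margin pixels are 0."""
    if not t > 0:
        raise ValueError(f"threshold T must be > 0, got {t}")
    out = np.zeros(field.values.shape, dtype=np.uint8)
    valid = field.valid_mask
    out[valid] = (field.values[valid] >= t).astype(np.uint8)
    return out
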