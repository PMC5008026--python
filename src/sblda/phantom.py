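"""Synthetic abdominal CT phantoms with exact ground-truth liver masks.

A phantom slice is built on the Hounsfield scale: an elliptical body of
soft tissue (~40 HU) on an air background (-1000 HU), a large liver
ellipse (~90 HU) placed against the left body wall, and an adjacent
neighbor organ of similar attenuation (~70 HU) against the right wall.
Organs are delineated by thin hypodense fat planes (~-100 HU), the way
real abdominal anatomy separates structures of nearly equal attenuation —
the "weak edges" that make liver segmentation hard.  Options add a bright
circular ring artifact hugging the body outline, a tumor inclusion inside
the liver (hypodense cancer-like or mildly hyperdense hemangioma-like),
additive Gaussian noise, and salt-and-pepper impulses.

The ground-truth mask is the liver ellipse itself (tumors count as liver),
exact by construction.  Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import List, Optional, Tuple

import numpy as np

from .io_config import CTSlice

__all__ = ["PhantomSpec", "generate_phantom", "generate_suite", "AIR_HU"]

AIR_HU = -1000.0


@dataclass
class PhantomSpec:
    """Geometry and intensity recipe for one phantom slice.

    Axes are (row, col) semi-axes in pixels; HU values sit inside the
    soft-tissue display window [-160, 240] so windowing does not clip the
    structures (except air, fat below -160 and bright artifacts, which
    clamp by design).  ``neighbor_gap`` is the boundary-to-boundary fat
    separation between liver and neighbor; ``rim_width``/``rim_hu`` set the
    peri-hepatic fat plane that carries the organ boundaries.
    """

    size: int = 256
    body_center: Tuple[float, float] = (128.0, 128.0)
    body_axes: Tuple[float, float] = (100.0, 105.0)
    liver_center: Tuple[float, float] = (128.0, 89.0)
    liver_axes: Tuple[float, float] = (70.0, 62.0)
    liver_hu: float = 90.0
    background_hu: float = 40.0
    neighbor_hu: float = 70.0
    neighbor_axes: Tuple[float, float] = (45.0, 39.0)
    neighbor_gap: float = 4.0
    rim_hu: float = -120.0
    rim_width: float = 4.0
    noise_sigma: float = 10.0
    salt_pepper: float = 0.0
    ring: bool = False
    ring_hu: float = 300.0
    ring_width: float = 3.0
    tumor: Optional[Tuple[Tuple[float, float], float, float]] = None  # (center, radius, hu)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        if not 0 <= self.salt_pepper < 1:
            raise ValueError(f"salt_pepper must be in [0, 1), got {self.salt_pepper}")
        if self.rim_width < 1:
            raise ValueError(f"rim_width must be >= 1, got {self.rim_width}")


def _ellipse_mask(
    shape: Tuple[int, int], center: Tuple[float, float], axes: Tuple[float, float]
) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _disk_mask(
    shape: Tuple[int, int], center: Tuple[float, float], radius: float
) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def ring_mask_pixels(spec: PhantomSpec) -> np.ndarray:
    """Pixels occupied by the ring artifact (empty if ``spec.ring`` is off)."""
    shape = (spec.size, spec.size)
    if not spec.ring:
        return np.zeros(shape, dtype=bool)
    r_in = max(spec.body_axes) + 1.0
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    d2 = (rr - spec.body_center[0]) ** 2 + (cc - spec.body_center[1]) ** 2
    band = (d2 >= r_in**2) & (d2 <= (r_in + spec.ring_width) ** 2)
    body = _ellipse_mask(shape, spec.body_center, spec.body_axes)
    return band & ~body


def generate_phantom(spec: PhantomSpec) -> Tuple[CTSlice, np.ndarray]:
    """Render one phantom; returns the HU slice and the exact liver mask."""
    shape = (spec.size, spec.size)
    body = _ellipse_mask(shape, spec.body_center, spec.body_axes)
    liver = _ellipse_mask(shape, spec.liver_center, spec.liver_axes)
    if not (liver <= body).all():
        raise ValueError("liver ellipse must lie fully inside the body region")
    liver_rim = (
        _ellipse_mask(
            shape,
            spec.liver_center,
            (spec.liver_axes[0] + spec.rim_width, spec.liver_axes[1] + spec.rim_width),
        )
        & ~liver
        & body
    )
    neighbor = _ellipse_mask(shape, _neighbor_center(spec), spec.neighbor_axes) & body
    neighbor_rim = (
        _ellipse_mask(
            shape,
            _neighbor_center(spec),
            (
                spec.neighbor_axes[0] + spec.rim_width,
                spec.neighbor_axes[1] + spec.rim_width,
            ),
        )
        & ~neighbor
        & body
    )
    if (neighbor & liver).any():
        raise ValueError("neighbor organ overlaps the liver; increase neighbor_gap")

    hu = np.full(shape, AIR_HU)
    hu[body] = spec.background_hu
    hu[liver_rim] = spec.rim_hu
    hu[neighbor_rim] = spec.rim_hu
    hu[liver] = spec.liver_hu
    hu[neighbor] = spec.neighbor_hu
    if spec.tumor is not None:
        t_center, t_radius, t_hu = spec.tumor
        tumor = _disk_mask(shape, t_center, t_radius)
        if not (tumor <= liver).all():
            raise ValueError("tumor must lie fully inside the liver")
        hu[tumor] = t_hu
    ring_px = ring_mask_pixels(spec)
    hu[ring_px] = spec.ring_hu

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        hu = hu + rng.normal(0.0, spec.noise_sigma, shape)
    if spec.salt_pepper > 0:
        k = int(round(spec.salt_pepper * hu.size))
        idx = rng.choice(hu.size, size=k, replace=False)
        vals = rng.choice([-1000.0, 1000.0], size=k)
        hu.ravel()[idx] = vals

    truth = liver.astype(np.uint8)
    return CTSlice(hu, spacing=(1.0, 1.0), needs_windowing=True), truth


def _neighbor_center(spec: PhantomSpec) -> Tuple[float, float]:
    """Neighbor organ centered at the liver's row, placed ``neighbor_gap``
    pixels to the right of the liver boundary (it may press against the
    right body wall, as bowel does)."""
    row = spec.liver_center[0]
    col = spec.liver_center[1] + spec.liver_axes[1] + spec.neighbor_gap + spec.neighbor_axes[1]
    return (row, col)


def _wall_cols(spec: PhantomSpec, row: float) -> Tuple[int, int]:
    """First and last body-pixel columns at a given row."""
    dr = (row - spec.body_center[0]) / spec.body_axes[0]
    half = spec.body_axes[1] * math.sqrt(max(0.0, 1.0 - dr * dr))
    return (
        math.ceil(spec.body_center[1] - half),
        math.floor(spec.body_center[1] + half),
    )


def generate_suite(
    n: int, mix: float = 0.5, seed: int = 0, **overrides
) -> List[Tuple[CTSlice, np.ndarray]]:
    """Generate ``n`` phantoms with randomized geometry; ``round(n * mix)``
    of them carry a tumor (half hypodense cancer-like, half mildly
    hyperdense hemangioma-like).  The liver stays pressed against the left
    body wall (its fat rim reaching the outline), as in axial anatomy.
    Reproducible for a fixed seed; ``overrides`` patch every spec.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0 <= mix <= 1:
        raise ValueError(f"mix must be in [0, 1], got {mix}")
    rng = np.random.default_rng(seed)
    n_tumor = int(round(n * mix))
    with_tumor = np.zeros(n, dtype=bool)
    with_tumor[:n_tumor] = True
    rng.shuffle(with_tumor)

    out: List[Tuple[CTSlice, np.ndarray]] = []
    base = PhantomSpec(**overrides) if overrides else PhantomSpec()
    for i in range(n):
        liver_axes = (
            float(base.liver_axes[0] + rng.integers(-5, 6)),
            float(base.liver_axes[1] + rng.integers(-4, 5)),
        )
        row = float(base.body_center[0] + rng.integers(-4, 5))
        seed_i = int(rng.integers(0, 2**31 - 1))
        left_col, right_col = _wall_cols(base, row)
        # liver pressed to the left wall: its fat rim reaches the outline
        col = float(left_col + base.rim_width + liver_axes[1])
        liver_max = col + liver_axes[1]
        # neighbor spans from the fat gap to (past) the right wall, so the
        # tissue between organs splits into separate upper/lower pools
        nac = math.ceil((right_col - liver_max - base.neighbor_gap) / 2.0) + 1.0
        neighbor_axes = (
            float(base.neighbor_axes[0] + rng.integers(-4, 5)),
            nac,
        )
        spec = replace(
            base,
            liver_center=(row, col),
            liver_axes=liver_axes,
            neighbor_axes=neighbor_axes,
            seed=seed_i,
        )
        if with_tumor[i]:
            t_center = (
                row + float(rng.integers(-8, 9)),
                col + float(rng.integers(-8, 9)),
            )
            t_radius = float(rng.integers(10, 15))
            t_hu = 45.0 if rng.random() < 0.5 else 115.0
            spec = replace(spec, tumor=(t_center, t_radius, t_hu))
        out.append(generate_phantom(spec))
    return out
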