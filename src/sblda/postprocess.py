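"""Morphological postprocessing: from edge evidence to one liver mask.

The confidence matrix is a web of boundary evidence.  Opening removes
speckle, the largest connected edge network is kept, and inverting plus
eroding it turns closed boundary contours into separate interior regions.
Intersecting those regions with the ring-artifact body mask M discards
everything outside the (morphologically opened) body, the anatomical rule
picks the liver — the largest region in the left part of the image — and a
Gaussian/median smoothing pass cleans and reconnects its boundary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage
from skimage import morphology
from skimage.filters import threshold_otsu

from .io_config import CTSlice, SBLDAParams, validate_mask
from .preprocess import DisplayImage, apply_window, display_from_raster, median_filter_2d
from .core import confidence_matrix, max_ratio_field

__all__ = [
    "ComponentLabeling",
    "SegmentationError",
    "label_components",
    "ring_artifact_mask",
    "remove_outliers",
    "largest_component",
    "invert_and_erode",
    "smooth_and_reconnect",
    "select_liver",
    "segment_liver",
]

#: Components whose centroid column is left of this fraction of the image
#: width count as "left region" for the anatomical selection rule.
LEFT_REGION_FRACTION = 0.6

_STRUCT_8 = np.ones((3, 3), dtype=bool)
_STRUCT_4 = ndimage.generate_binary_structure(2, 1)


class SegmentationError(RuntimeError):
    """Pipeline failure, naming the stage that produced an empty result."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class ComponentLabeling:
    """Connected components of a binary mask (label 0 = background)."""

    labels: np.ndarray
    sizes: np.ndarray  # sizes[k] = pixel count of label k+1
    centroids: np.ndarray  # centroids[k] = (row, col) of label k+1

    @property
    def n_components(self) -> int:
        return len(self.sizes)

    def mask_of(self, label: int) -> np.ndarray:
        return (self.labels == label).astype(np.uint8)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return _STRUCT_8
    if connectivity == 4:
        return _STRUCT_4
    raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")


def label_components(mask: np.ndarray, connectivity: int = 8) -> ComponentLabeling:
    arr = validate_mask(mask)
    labels, n = ndimage.label(arr, structure=_structure(connectivity))
    if n == 0:
        return ComponentLabeling(labels, np.zeros(0, dtype=np.int64), np.zeros((0, 2)))
    sizes = np.bincount(labels.ravel())[1:]
    centroids = np.asarray(ndimage.center_of_mass(arr, labels, np.arange(1, n + 1)))
    return ComponentLabeling(labels, sizes.astype(np.int64), centroids)


def _disk(radius: int) -> np.ndarray:
    return morphology.disk(radius).astype(bool)


def ring_artifact_mask(image: DisplayImage, radius: int) -> np.ndarray:
    """Body mask M used to reject ring artifacts.

    The display image is thresholded (Otsu) to separate the body from air,
    thin gaps are closed, the largest component is kept and hole-filled to a
    solid body, and a morphological opening with a disk of the given radius
    shaves off thin bright appendages such as ring artifacts hugging the
    body outline.  M = 1 inside the opened body.
    """
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    px = image.pixels
    if px.max() == px.min():
        raise SegmentationError("ring_mask", "image is constant; no body/background split")
    fg = px > threshold_otsu(px)
    if not fg.any():
        raise SegmentationError("ring_mask", "empty foreground after thresholding")
    # seal narrow dark interfaces (fat planes reaching the outline) so the
    # body stays one piece: radius 3 seals plane-width (~4 px) gaps at any
    # orientation while a clearly detached ring artifact (moat > 6 px)
    # stays separate.  Erosions treat outside-image as foreground so a body
    # reaching the frame is not shaved there
    struct3 = _disk(3)
    fg = ndimage.binary_erosion(
        ndimage.binary_dilation(fg, structure=struct3, border_value=0),
        structure=struct3,
        border_value=1,
    )
    labeling = label_components(fg.astype(np.uint8), connectivity=8)
    body = labeling.mask_of(int(np.argmax(labeling.sizes)) + 1).astype(bool)
    struct = _disk(radius)
    opened = ndimage.binary_dilation(
        ndimage.binary_erosion(body, structure=struct, border_value=1),
        structure=struct,
        border_value=0,
    )
    if not opened.any():
        raise SegmentationError("ring_mask", f"body vanished under opening (radius {radius})")
    # solidify: interior holes (dark organ interfaces, artifact moats) are body
    return ndimage.binary_fill_holes(opened).astype(np.uint8)


def remove_outliers(mask: np.ndarray, radius: int) -> np.ndarray:
    """Morphological opening with a disk: removes structures thinner than it."""
    if radius < 1:
        raise ValueError(f"radius must be >= 1, got {radius}")
    arr = validate_mask(mask)
    return ndimage.binary_opening(arr, structure=_disk(radius), border_value=0).astype(np.uint8)


def largest_component(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Keep only the largest connected component.

    Ties break to the smallest centroid column (leftmost), then the
    smallest label.
    """
    labeling = label_components(mask, connectivity)
    if labeling.n_components == 0:
        raise SegmentationError("largest_component", "mask has no positive pixels")
    best = _pick_largest(labeling)
    return labeling.mask_of(best)


def _pick_largest(labeling: ComponentLabeling, candidates: Optional[np.ndarray] = None) -> int:
    """Label of the largest component (ties: leftmost centroid, then label)."""
    idx = np.arange(labeling.n_components) if candidates is None else np.asarray(candidates)
    sizes = labeling.sizes[idx]
    top = idx[sizes == sizes.max()]
    cols = labeling.centroids[top, 1]
    return int(top[np.lexsort((top, cols))[0]]) + 1


def invert_and_erode(edge_mask: np.ndarray, radius: int) -> np.ndarray:
    """Complement the edge mask and erode with a disk.

    Turns closed edge contours into interior regions disconnected from the
    surrounding background.  Erosion treats outside-image as background, so
    the result also shrinks away from the frame.
    """
    arr = validate_mask(edge_mask)
    inv = arr == 0
    return ndimage.binary_erosion(inv, structure=_disk(radius), border_value=0).astype(np.uint8)


def smooth_and_reconnect(mask: np.ndarray, sigma: float, reconnect_window: int) -> np.ndarray:
    """Gaussian-smooth the mask boundary, then median-filter to close gaps.

    The blurred mask is re-binarized at 0.5 (majority), and the median step
    (a majority vote over the reconnect window) closes slits and pinholes.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if reconnect_window < 1 or reconnect_window % 2 == 0:
        raise ValueError(f"reconnect_window must be odd and >= 1, got {reconnect_window}")
    arr = validate_mask(mask)
    blurred = ndimage.gaussian_filter(arr.astype(np.float64), sigma)
    binar = (blurred >= 0.5).astype(np.uint8)
    return ndimage.median_filter(binar, size=reconnect_window, mode="nearest").astype(np.uint8)


def select_liver(labeling: ComponentLabeling, image_shape: Tuple[int, int]) -> np.ndarray:
    """Anatomical liver selection.

    The liver occupies the left region of an abdominal slice (patient right,
    image left under radiological display) and is the largest structure
    there: among components whose centroid column is left of
    ``LEFT_REGION_FRACTION`` x width, the largest wins.  If no component is
    in the left region, fall back to the overall largest with a warning.
    """
    if labeling.n_components == 0:
        raise SegmentationError("select_liver", "no candidate components")
    width = image_shape[1]
    in_left = np.flatnonzero(labeling.centroids[:, 1] < LEFT_REGION_FRACTION * width)
    if len(in_left) == 0:
        warnings.warn(
            "no component in the left region; falling back to overall largest",
            stacklevel=2,
        )
        best = _pick_largest(labeling)
    else:
        best = _pick_largest(labeling, in_left)
    return labeling.mask_of(best)


def segment_liver(
    ct: CTSlice,
    params: Optional[SBLDAParams] = None,
    use_ring_mask: bool = True,
    intermediates: Optional[dict] = None,
) -> np.ndarray:
    """Full pipeline: one CT slice in, one binary liver mask out.

    Deterministic for fixed inputs.  ``intermediates``, if a dict, receives
    each stage's output under a descriptive key.  ``use_ring_mask=False``
    skips the body-mask intersection (for studying ring-artifact handling).

    Raises :class:`SegmentationError` naming the stage if any stage empties
    the mask.
    """
    params = params or SBLDAParams()

    if ct.needs_windowing:
        display = apply_window(ct, params.window_width, params.window_level)
    else:
        display = display_from_raster(ct)
    denoised = median_filter_2d(display, params.median_window)

    field = max_ratio_field(denoised, params)
    conf = confidence_matrix(field, params.T)
    if not conf.any():
        raise SegmentationError("confidence", f"no edge evidence at T={params.T}")

    opened = remove_outliers(conf, params.outlier_radius)
    if not opened.any():
        raise SegmentationError("remove_outliers", "edge mask vanished under opening")
    edges = largest_component(opened, connectivity=8)

    regions = invert_and_erode(edges, params.outlier_radius)
    if not regions.any():
        raise SegmentationError("invert_and_erode", "no interior regions")

    if use_ring_mask:
        body = ring_artifact_mask(display, params.ring_radius)
        candidates = (regions & body).astype(np.uint8)
        if not candidates.any():
            raise SegmentationError("ring_mask", "no candidate region inside the body mask")
    else:
        body = np.ones_like(regions, dtype=np.uint8)
        candidates = regions

    labeling = label_components(candidates, connectivity=8)
    liver = select_liver(labeling, candidates.shape)

    # restore the extent removed by the disconnecting erosion, then smooth
    liver = ndimage.binary_dilation(
        liver.astype(bool), structure=_disk(params.outlier_radius), border_value=0
    ).astype(np.uint8)
    liver = smooth_and_reconnect(liver, params.gaussian_sigma, params.reconnect_window)
    liver = (liver & body).astype(np.uint8)
    if not liver.any():
        raise SegmentationError("smooth_and_reconnect", "liver mask vanished during smoothing")
    liver = largest_component(liver, connectivity=8)

    if intermediates is not None:
        intermediates.update(
            windowed=display.pixels,
            denoised=denoised.pixels,
            ratio_field=field.values,
            confidence=conf,
            outliers_removed=opened,
            edge_component=edges,
            interior_regions=regions,
            body_mask=body,
            candidates=candidates,
            liver=liver,
        )
    return liver
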