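"""Segmentation evaluation metrics.

Confusion-matrix measures (sensitivity, specificity, accuracy) plus the
five volume/surface measures customary in liver-segmentation benchmarking:
volumetric overlap error (VOE), signed relative volume difference (SRVD),
and the average / root-mean-square / maximum symmetric surface distances
(ASD, RMSD, MSD) in millimetres.

All metrics here are 2D per-slice: masks are pixel sets, borders are
positive pixels with a background 4-neighbor (outside the image counts as
background), and distances are Euclidean in physical units via the pixel
spacing.  Surface distances pool both directed nearest-border distance
sets, so ASD/RMSD/MSD are symmetric; SRVD is signed, positive meaning
oversegmentation of the prediction relative to the reference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .io_config import CTSlice, SBLDAParams, validate_mask

__all__ = [
    "SegReport",
    "confusion_metrics",
    "volume_metrics",
    "surface_distance_metrics",
    "dice",
    "evaluate_masks",
    "threshold_sweep",
]


@dataclass
class SegReport:
    """Evaluation of a (predicted, reference) mask pair.

    Ratio fields are ``None`` when undefined (empty class), never silently
    0 or NaN.  Surface/volume fields are ``None`` until populated.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    accuracy: Optional[float]
    voe: Optional[float] = None
    srvd: Optional[float] = None
    asd: Optional[float] = None
    rmsd: Optional[float] = None
    msd: Optional[float] = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def _check_shapes(pred: np.ndarray, ref: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    p = validate_mask(pred)
    r = validate_mask(ref)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: pred {p.shape} vs ref {r.shape}")
    return p, r


def confusion_metrics(pred: np.ndarray, ref: np.ndarray) -> SegReport:
    """Pixel confusion counts and sensitivity/specificity/accuracy.

    sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
    accuracy = (TP+TN)/(P+N) over all pixels.
    """
    p, r = _check_shapes(pred, ref)
    pb, rb = p.astype(bool), r.astype(bool)
    tp = int(np.count_nonzero(pb & rb))
    tn = int(np.count_nonzero(~pb & ~rb))
    fp = int(np.count_nonzero(pb & ~rb))
    fn = int(np.count_nonzero(~pb & rb))
    total = p.size
    sens = tp / (tp + fn) if tp + fn > 0 else None
    spec = tn / (tn + fp) if tn + fp > 0 else None
    acc = (tp + tn) / total if total > 0 else None
    return SegReport(tp=tp, tn=tn, fp=fp, fn=fn, sensitivity=sens, specificity=spec, accuracy=acc)


def volume_metrics(pred: np.ndarray, ref: np.ndarray) -> Tuple[float, float]:
    """VOE and SRVD in percent.

    VOE = 100 * (1 - |A n B| / |A u B|); SRVD = 100 * (|A| - |B|) / |B|
    with A the prediction and B the reference (signed, not symmetric).
    """
    p, r = _check_shapes(pred, ref)
    pb, rb = p.astype(bool), r.astype(bool)
    nb = int(np.count_nonzero(rb))
    if nb == 0:
        raise ValueError("reference mask is empty")
    inter = int(np.count_nonzero(pb & rb))
    union = int(np.count_nonzero(pb | rb))
    voe = 100.0 * (1.0 - inter / union)
    srvd = 100.0 * (int(np.count_nonzero(pb)) - nb) / nb
    return voe, srvd


def dice(pred: np.ndarray, ref: np.ndarray) -> float:
    """Dice overlap 2|A n B| / (|A| + |B|); 1.0 for two empty masks."""
    p, r = _check_shapes(pred, ref)
    pb, rb = p.astype(bool), r.astype(bool)
    denom = int(np.count_nonzero(pb)) + int(np.count_nonzero(rb))
    if denom == 0:
        return 1.0
    return 2.0 * int(np.count_nonzero(pb & rb)) / denom


_CROSS = ndimage.generate_binary_structure(2, 1)


def _border_coords(mask: np.ndarray) -> np.ndarray:
    """Coordinates of positive pixels with >= 1 background 4-neighbor
    (outside the image counts as background)."""
    b = mask.astype(bool)
    interior = ndimage.binary_erosion(b, structure=_CROSS, border_value=0)
    return np.argwhere(b & ~interior)


def surface_distance_metrics(
    pred: np.ndarray, ref: np.ndarray, spacing: Tuple[float, float] = (1.0, 1.0)
) -> Tuple[float, float, float]:
    """ASD, RMSD and MSD between the two mask borders, in mm.

    Both directed nearest-neighbor distance sets (pred border -> ref border
    and ref border -> pred border) are pooled; ASD is the mean, RMSD the
    root mean square and MSD the maximum of the pool.
    """
    p, r = _check_shapes(pred, ref)
    if not p.any() or not r.any():
        raise ValueError("surface distances require both masks nonempty")
    sp = np.asarray(spacing, dtype=np.float64)
    if (sp <= 0).any():
        raise ValueError(f"spacing must be positive, got {spacing}")
    bp = _border_coords(p) * sp
    br = _border_coords(r) * sp
    d_pr = cKDTree(br).query(bp)[0]
    d_rp = cKDTree(bp).query(br)[0]
    pooled = np.concatenate([d_pr, d_rp])
    asd = float(pooled.mean())
    rmsd = float(np.sqrt(np.mean(pooled**2)))
    msd = float(pooled.max())
    return asd, rmsd, msd


def evaluate_masks(
    pred: np.ndarray, ref: np.ndarray, spacing: Tuple[float, float] = (1.0, 1.0)
) -> SegReport:
    """Full report: confusion, volume and surface metrics for a mask pair."""
    report = confusion_metrics(pred, ref)
    if ref.any():
        report.voe, report.srvd = volume_metrics(pred, ref)
        if pred.any():
            report.asd, report.rmsd, report.msd = surface_distance_metrics(pred, ref, spacing)
    return report


def threshold_sweep(
    phantom_set: Sequence[Tuple[CTSlice, np.ndarray]],
    t_values: Sequence[float],
    params: Optional[SBLDAParams] = None,
) -> List[Tuple[float, float]]:
    """Mean segmentation accuracy over a phantom set for each threshold T.

    Runs the full pipeline at each T.  A pipeline failure (no usable edge
    structure at that threshold) scores as an empty prediction, so gross
    failures show up as the background-only accuracy rather than aborting
    the sweep.  Returns ``[(T, mean_accuracy), ...]``.
    """
    from .postprocess import SegmentationError, segment_liver

    if len(phantom_set) == 0 or len(t_values) == 0:
        raise ValueError("phantom_set and t_values must be nonempty")
    base = params or SBLDAParams()
    rows: List[Tuple[float, float]] = []
    for t in t_values:
        p = base.replace(T=float(t))
        accs = []
        for ct, truth in phantom_set:
            try:
                mask = segment_liver(ct, p)
            except SegmentationError:
                mask = np.zeros_like(truth, dtype=np.uint8)
            accs.append(confusion_metrics(mask, truth).accuracy)
        rows.append((float(t), float(np.mean(accs))))
    return rows
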