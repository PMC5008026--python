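"""Input/output plumbing and parameter handling.

CT slices enter as DICOM files (single slice), NIfTI volumes (a slice index
selects the axial plane), or plain grayscale rasters (PNG/TIFF) used for
phantoms.  DICOM and NIfTI pixels are interpreted on the Hounsfield scale;
raster pixels are taken as already display-scaled and flagged as such so the
pipeline skips intensity windowing.

Coordinate convention throughout the package: row-major arrays, 0-based
indices, origin at the top-left corner; "left of the image" means the lowest
column indices.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Optional, Tuple

import imageio.v3 as iio
import numpy as np
import yaml

__all__ = [
    "CTSlice",
    "SBLDAParams",
    "DEFAULT_DIRECTIONS",
    "read_ct_slice",
    "write_mask",
    "read_mask",
    "load_params",
    "validate_mask",
]

#: The eight detection directions, in degrees.
DEFAULT_DIRECTIONS: Tuple[float, ...] = (0.0, 45.0, 90.0, 135.0, 180.0, 225.0, 270.0, 315.0)

_ORIGIN_NOTE = "row-major, 0-based, origin top-left; +col is image right"


@dataclass
class CTSlice:
    """A single 2D CT slice.

    Parameters
    ----------
    pixels
        2D array of intensities.  Hounsfield units unless
        ``needs_windowing`` is False (raster/phantom input already on the
        display scale).
    spacing
        Physical pixel size in mm, ``(row, col)``.
    origin_note
        Free-text tag recording the orientation convention.
    needs_windowing
        True when the pixels are HU and must be windowed before detection.
    """

    pixels: np.ndarray
    spacing: Tuple[float, float] = (1.0, 1.0)
    origin_note: str = _ORIGIN_NOTE
    needs_windowing: bool = True

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2:
            raise ValueError(f"CTSlice.pixels must be 2D, got shape {px.shape}")
        if not np.all(np.isfinite(px)):
            raise ValueError("CTSlice.pixels must be finite-valued")
        self.pixels = px
        r, c = float(self.spacing[0]), float(self.spacing[1])
        if r <= 0 or c <= 0:
            raise ValueError(f"CTSlice.spacing must be positive, got {self.spacing}")
        self.spacing = (r, c)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]


@dataclass
class SBLDAParams:
    """Tunable parameters of the detection pipeline.

    Defaults are the operating point used for abdominal CT: ratio threshold
    ``T = 0.85`` with a detection window ``w = 9`` and block size ``N = 3``
    over the eight principal directions, soft-tissue display window
    width/level 400/40 HU, a 5x5 median denoising filter, disk radii of
    2 px (outlier removal / region erosion) and 20 px (ring-artifact mask),
    and Gaussian sigma 2 px with a 5 px median reconnection window for the
    final boundary smoothing.
    """

    T: float = 0.85
    w: int = 9
    N: int = 3
    directions: Tuple[float, ...] = DEFAULT_DIRECTIONS
    window_width: float = 400.0
    window_level: float = 40.0
    median_window: int = 5
    outlier_radius: int = 2
    ring_radius: int = 20
    gaussian_sigma: float = 2.0
    reconnect_window: int = 5
    #: "along": flanking blocks lie on the detection direction axis (default);
    #: "perpendicular": blocks flank the candidate at right angles to it
    #: (classic line-operator variant, exposed for experimentation only).
    block_orientation: str = "along"

    def __post_init__(self) -> None:
        if not self.T > 0:
            raise ValueError(f"T must be > 0, got {self.T}")
        if self.w < 3 or self.w % 2 == 0:
            raise ValueError(f"w must be odd and >= 3, got {self.w}")
        if self.N < 1 or self.N % 2 == 0:
            raise ValueError(f"N must be odd and >= 1, got {self.N}")
        if self.N > self.w:
            raise ValueError(f"N must be <= w, got N={self.N}, w={self.w}")
        if not self.window_width > 0:
            raise ValueError(f"window_width must be > 0, got {self.window_width}")
        if self.median_window < 1 or self.median_window % 2 == 0:
            raise ValueError(f"median_window must be odd and >= 1, got {self.median_window}")
        if self.reconnect_window < 1 or self.reconnect_window % 2 == 0:
            raise ValueError(f"reconnect_window must be odd and >= 1, got {self.reconnect_window}")
        for name in ("outlier_radius", "ring_radius"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if not self.gaussian_sigma > 0:
            raise ValueError(f"gaussian_sigma must be > 0, got {self.gaussian_sigma}")
        if self.block_orientation not in ("along", "perpendicular"):
            raise ValueError(
                f"block_orientation must be 'along' or 'perpendicular', got {self.block_orientation!r}"
            )
        self.directions = tuple(float(d) for d in self.directions)
        if len(self.directions) == 0:
            raise ValueError("directions must be nonempty")

    def replace(self, **kwargs) -> "SBLDAParams":
        return replace(self, **kwargs)


def validate_mask(mask: np.ndarray) -> np.ndarray:
    """Check a binary mask (values strictly in {0, 1}) and return it as uint8."""
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError(f"mask must be 2D, got shape {arr.shape}")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("mask values must be strictly in {0, 1}")
    return arr.astype(np.uint8)


# --------------------------------------------------------------------------
# readers / writers

def _read_dicom(path: Path) -> CTSlice:
    import pydicom

    ds = pydicom.dcmread(str(path))
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    hu = arr * slope + intercept
    spacing = getattr(ds, "PixelSpacing", None)
    if spacing is None:
        warnings.warn(f"{path}: no PixelSpacing tag; assuming 1x1 mm", stacklevel=3)
        sp = (1.0, 1.0)
    else:
        sp = (float(spacing[0]), float(spacing[1]))
    return CTSlice(hu, spacing=sp, needs_windowing=True)


def _read_nifti(path: Path, slice_index: Optional[int]) -> CTSlice:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.float64)
    zooms = img.header.get_zooms()
    if data.ndim == 3:
        if slice_index is None:
            raise ValueError(f"{path}: NIfTI volume requires slice_index")
        if not 0 <= slice_index < data.shape[2]:
            raise ValueError(
                f"slice_index {slice_index} out of range for volume with {data.shape[2]} planes"
            )
        plane = data[:, :, slice_index]
    elif data.ndim == 2:
        plane = data
    else:
        raise ValueError(f"{path}: expected 2D or 3D NIfTI, got {data.ndim}D")
    sp = (float(zooms[0]), float(zooms[1])) if len(zooms) >= 2 else (1.0, 1.0)
    if sp[0] <= 0 or sp[1] <= 0:
        warnings.warn(f"{path}: non-positive zooms in header; assuming 1x1 mm", stacklevel=3)
        sp = (1.0, 1.0)
    return CTSlice(plane, spacing=sp, needs_windowing=True)


def _read_raster(path: Path) -> CTSlice:
    arr = iio.imread(str(path))
    if arr.ndim == 3:  # RGB(A) -> first channel (phantom rasters are gray)
        arr = arr[..., 0]
    return CTSlice(arr.astype(np.float64), spacing=(1.0, 1.0), needs_windowing=False)


_SUFFIX_FORMAT = {
    ".dcm": "dicom",
    ".dicom": "dicom",
    ".nii": "nifti",
    ".png": "raster",
    ".tif": "raster",
    ".tiff": "raster",
}


def _infer_format(path: Path) -> str:
    if path.name.endswith(".nii.gz"):
        return "nifti"
    fmt = _SUFFIX_FORMAT.get(path.suffix.lower())
    if fmt is None:
        raise ValueError(f"cannot infer format from {path.name}; pass format= explicitly")
    return fmt


def read_ct_slice(
    path, format: Optional[str] = None, slice_index: Optional[int] = None
) -> CTSlice:
    """Read a 2D CT slice from a DICOM, NIfTI or raster file.

    Raster input is taken as already display-scaled (``needs_windowing`` is
    False); DICOM rescale slope/intercept are applied so pixels are HU.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    fmt = format or _infer_format(p)
    if fmt == "dicom":
        return _read_dicom(p)
    if fmt == "nifti":
        return _read_nifti(p, slice_index)
    if fmt == "raster":
        return _read_raster(p)
    raise ValueError(f"unknown format {fmt!r}; expected dicom, nifti or raster")


def write_mask(mask: np.ndarray, path) -> None:
    """Write a binary mask as an 8-bit raster (0 / 255); lossless round-trip."""
    arr = validate_mask(mask)
    iio.imwrite(str(Path(path)), (arr * 255).astype(np.uint8))


def read_mask(path) -> np.ndarray:
    """Read a binary mask written by :func:`write_mask` (any nonzero -> 1)."""
    arr = iio.imread(str(Path(path)))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return (arr > 127).astype(np.uint8)


def load_params(path=None) -> SBLDAParams:
    """Load :class:`SBLDAParams` from a flat key-value (YAML) config file.

    Unspecified fields take the defaults; unknown keys are rejected.
    ``path=None`` returns the full default parameter set.
    """
    if path is None:
        return SBLDAParams()
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config must be a flat key-value mapping")
    known = {f.name for f in fields(SBLDAParams)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    if "directions" in data:
        data["directions"] = tuple(float(d) for d in data["directions"])
    return SBLDAParams(**data)
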