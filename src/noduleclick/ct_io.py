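"""CT slice and mask I/O, and the stored-value → Hounsfield-unit transform.

A CT detector stores integer values; the calibrated attenuation scale is the
Hounsfield unit (HU: air ≈ −1000, water = 0, soft tissue ≈ 0–100).  The two are
related by the affine map ``Hu = B + M * SV`` where ``B`` is the rescale
intercept and ``M`` the rescale slope, carried by DICOM metadata.  Everything
downstream (threshold calibration, region growing) works in HU, so this module
is the only place stored values appear.

Coordinates are 0-based (row, col); masks always share the image shape and no
resampling is ever performed.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)


class InvalidMetadataError(ValueError):
    """Raised when rescale metadata is non-finite or otherwise unusable."""


@dataclass(frozen=True)
class CTSlice:
    """A single 2-D CT slice in stored (detector) values plus rescale metadata.

    Parameters
    ----------
    stored_values : 2-D integer array, rows x cols.
    rescale_intercept : B, in HU.
    rescale_slope : M, in HU per stored unit.
    spacing : optional (row_mm, col_mm) pixel spacing.
    """

    stored_values: np.ndarray
    rescale_intercept: float = 0.0
    rescale_slope: float = 1.0
    spacing: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        sv = np.asarray(self.stored_values)
        if sv.ndim != 2 or sv.size == 0:
            raise ValueError("stored_values must be a non-empty 2-D grid")
        object.__setattr__(self, "stored_values", sv)
        if not (np.isfinite(self.rescale_intercept) and np.isfinite(self.rescale_slope)):
            raise InvalidMetadataError("rescale intercept/slope must be finite")
        if self.spacing is not None and not all(s > 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.stored_values.shape


@dataclass(frozen=True)
class HUImage:
    """A 2-D real-valued grid in Hounsfield units."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("values must be a non-empty 2-D grid")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass(frozen=True)
class BinaryMask:
    """A 2-D boolean grid annotating an image of the same shape."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values).astype(bool)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("mask must be a non-empty 2-D grid")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def area(self) -> int:
        return int(self.values.sum())

    @property
    def is_empty(self) -> bool:
        return not bool(self.values.any())


def to_hounsfield(ct: CTSlice) -> HUImage:
    """Convert stored values to Hounsfield units, ``Hu = B + M * SV``."""
    if not (np.isfinite(ct.rescale_intercept) and np.isfinite(ct.rescale_slope)):
        raise InvalidMetadataError("rescale intercept/slope must be finite")
    hu = ct.rescale_intercept + ct.rescale_slope * ct.stored_values.astype(float)
    return HUImage(hu)


def _read_dicom(path: Path) -> CTSlice:
    import pydicom

    ds = pydicom.dcmread(str(path), force=True)
    sv = ds.pixel_array
    b = getattr(ds, "RescaleIntercept", None)
    m = getattr(ds, "RescaleSlope", None)
    if b is None or m is None:
        warnings.warn(
            f"{path}: missing RescaleIntercept/RescaleSlope, defaulting to B=0, M=1",
            stacklevel=3,
        )
        logger.warning("%s: missing rescale tags, defaulting to B=0, M=1", path)
        b = 0.0 if b is None else b
        m = 1.0 if m is None else m
    spacing = None
    ps = getattr(ds, "PixelSpacing", None)
    if ps is not None:
        spacing = (float(ps[0]), float(ps[1]))
    return CTSlice(np.asarray(sv), float(b), float(m), spacing)


def _read_raw(path: Path) -> CTSlice:
    """Raw array (.npy or whitespace text) with a JSON sidecar ``<stem>.json``.

    Sidecar keys: ``rescale_intercept``, ``rescale_slope``, optional ``spacing``.
    """
    if path.suffix == ".npy":
        sv = np.load(path)
    else:
        sv = np.loadtxt(path)
    sidecar = path.with_suffix(".json")
    b, m, spacing = 0.0, 1.0, None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        b = float(meta.get("rescale_intercept", 0.0))
        m = float(meta.get("rescale_slope", 1.0))
        if "spacing" in meta:
            spacing = tuple(float(s) for s in meta["spacing"])
    else:
        warnings.warn(f"{path}: no sidecar metadata, defaulting to B=0, M=1", stacklevel=3)
    return CTSlice(np.asarray(sv), b, m, spacing)


def read_slice(path: str | Path, format: str | None = None) -> CTSlice:
    """Read a single CT slice.

    ``format`` is ``"dicom"`` or ``"raw"``; when omitted it is inferred from
    the suffix (``.dcm``/``.dicom`` → DICOM, otherwise raw array + sidecar).
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if format is None:
        format = "dicom" if path.suffix.lower() in {".dcm", ".dicom"} else "raw"
    if format == "dicom":
        return _read_dicom(path)
    if format == "raw":
        return _read_raw(path)
    raise ValueError(f"unknown slice format {format!r}")


def read_mask(path: str | Path, reference_shape: tuple[int, int] | None = None) -> BinaryMask:
    """Read a binary mask from PNG (any nonzero → True) or NIfTI.

    If ``reference_shape`` is given, a shape mismatch raises ``ValueError``.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    if path.suffix in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        import nibabel as nib

        arr = np.asanyarray(nib.load(str(path)).dataobj)
        arr = np.squeeze(arr)
    else:
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3:  # collapse any channel axis
            arr = arr[..., 0]
    mask = BinaryMask(arr != 0)
    if reference_shape is not None and mask.shape != tuple(reference_shape):
        raise ValueError(f"mask shape {mask.shape} != reference {tuple(reference_shape)}")
    return mask


def write_mask(mask: BinaryMask, path: str | Path) -> None:
    """Write a mask as 0/255 PNG or as NIfTI, by suffix.  write∘read is identity."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix in {".nii", ".gz"} or path.name.endswith(".nii.gz"):
        import nibabel as nib

        img = nib.Nifti1Image(mask.values.astype(np.uint8), affine=np.eye(4))
        nib.save(img, str(path))
    else:
        import imageio.v3 as iio

        iio.imwrite(path, (mask.values.astype(np.uint8) * 255))
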