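"""Thresholding-based morphology (TM): the lung-constrained click-seeded segmenter.

The pipeline, given an HU image, a lung mask, and a clicked pixel:

1. derive the adaptive threshold from the clicked HU value (calibration chain);
2. grow the 8-connected region of pixels with ``hu >= threshold`` inside the
   lung, starting from the click;
3. erode (3x3, 1 iteration) to cut thin bridges between nodule and non-nodule;
4. remove noise: keep only the connected component that contains the click;
5. dilate (3x3, 1 iteration) to restore the eroded boundary.

An empty final mask flags the result null, which is the switch that hands the
case to the candidate-fusion fallback (see ``candidate_fusion``).  Nodules
attached to the pleural wall typically fail here because the lung mask cuts
them off — by design.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import ndimage

from .calibration import ThresholdCalibration
from .ct_io import BinaryMask, HUImage

#: 3x3 all-ones structuring element — 8-connectivity everywhere in this module.
_STRUCT8 = np.ones((3, 3), dtype=bool)


class Provenance(str, Enum):
    TM = "TM"
    FALLBACK = "FALLBACK"


@dataclass(frozen=True)
class ClickSeed:
    """The user's clicked pixel: 0-based (row, col) and the HU value there."""

    row: int
    col: int
    start_hu: float

    def in_bounds(self, shape: tuple[int, int]) -> bool:
        return 0 <= self.row < shape[0] and 0 <= self.col < shape[1]


@dataclass(frozen=True)
class SegmentationResult:
    """A segmentation plus its provenance (TM or FALLBACK) and threshold."""

    mask: BinaryMask
    provenance: Provenance
    threshold_used: float | None = None
    is_null: bool = False

    def __post_init__(self) -> None:
        if self.is_null != self.mask.is_empty:
            raise ValueError("is_null must mirror mask emptiness")
        if self.provenance is Provenance.TM and self.threshold_used is None:
            raise ValueError("TM results must carry the threshold used")


def _check_shapes(hu: HUImage, *masks: BinaryMask) -> None:
    for m in masks:
        if m.shape != hu.shape:
            raise ValueError(f"mask shape {m.shape} != image shape {hu.shape}")


def grow_region(hu: HUImage, lung: BinaryMask, seed: ClickSeed, threshold: float) -> BinaryMask:
    """Seeded region growing: the 8-connected component of
    ``{p : hu(p) >= threshold and lung(p)}`` containing the seed.

    The threshold is a lower bound only; there is no upper HU bound.  Returns
    an empty mask when the seed pixel itself fails either condition.
    """
    _check_shapes(hu, lung)
    if not seed.in_bounds(hu.shape):
        raise ValueError(f"seed {seed.row, seed.col} outside image {hu.shape}")
    admissible = (hu.values >= threshold) & lung.values
    if not admissible[seed.row, seed.col]:
        return BinaryMask(np.zeros(hu.shape, dtype=bool))
    labels, _ = ndimage.label(admissible, structure=_STRUCT8)
    return BinaryMask(labels == labels[seed.row, seed.col])


def _check_kernel(kernel_size: int) -> np.ndarray:
    if kernel_size % 2 == 0 or kernel_size < 1:
        raise ValueError("kernel size must be odd and positive")
    return np.ones((kernel_size, kernel_size), dtype=bool)


def erode(mask: BinaryMask, kernel_size: int = 3, iterations: int = 1) -> BinaryMask:
    """Binary erosion with a square all-ones kernel; outside the grid is background."""
    st = _check_kernel(kernel_size)
    out = ndimage.binary_erosion(mask.values, structure=st, iterations=iterations,
                                 border_value=0)
    return BinaryMask(out)


def dilate(mask: BinaryMask, kernel_size: int = 3, iterations: int = 1) -> BinaryMask:
    """Binary dilation with a square all-ones kernel."""
    st = _check_kernel(kernel_size)
    out = ndimage.binary_dilation(mask.values, structure=st, iterations=iterations,
                                  border_value=0)
    return BinaryMask(out)


def remove_noise(mask: BinaryMask, seed: ClickSeed) -> BinaryMask:
    """Drop every 8-connected component except the one holding the click.

    "Noise" here means any segmented area that does not include the user's
    click.  If erosion has pushed the click out of every component, the
    component whose centroid is nearest the click (Euclidean) is kept instead,
    the least destructive reading of the rule.  Empty input stays empty.
    """
    if mask.is_empty:
        return mask
    labels, n = ndimage.label(mask.values, structure=_STRUCT8)
    if seed.in_bounds(mask.shape) and labels[seed.row, seed.col] != 0:
        keep = labels[seed.row, seed.col]
    else:
        centroids = ndimage.center_of_mass(mask.values, labels, range(1, n + 1))
        d2 = [(cr - seed.row) ** 2 + (cc - seed.col) ** 2 for cr, cc in centroids]
        keep = int(np.argmin(d2)) + 1
    return BinaryMask(labels == keep)


def tm_segment(
    hu: HUImage,
    lung: BinaryMask,
    seed: ClickSeed,
    calib: ThresholdCalibration,
) -> SegmentationResult:
    """Full TM pipeline: threshold → grow → erode → remove noise → dilate.

    The final mask is always a subset of the lung intersected with the
    above-threshold set (dilation is clipped back to the grown region), and
    ``is_null`` is set whenever any stage empties the mask — the signal that
    the fallback segmenter should take over.
    """
    threshold = calib.threshold_for(seed.start_hu)
    grown = grow_region(hu, lung, seed, threshold)
    if grown.is_empty:
        return SegmentationResult(grown, Provenance.TM, threshold, is_null=True)
    eroded = erode(grown)
    if eroded.is_empty:
        empty = BinaryMask(np.zeros(hu.shape, dtype=bool))
        return SegmentationResult(empty, Provenance.TM, threshold, is_null=True)
    cleaned = remove_noise(eroded, seed)
    final = dilate(cleaned)
    # dilation may not leak outside the admissible grown region
    final = BinaryMask(final.values & grown.values)
    return SegmentationResult(final, Provenance.TM, threshold, is_null=final.is_empty)


def fallback_lung_mask(hu: HUImage, air_threshold: float = -500.0) -> BinaryMask:
    """Classical lung masker for phantoms and demos (not a learned model).

    Pixels below ``air_threshold`` HU that do not touch the image border are
    candidate lung; the two largest interior components are kept and their
    holes filled, so nodules denser than the threshold stay inside the mask.
    """
    low = hu.values < air_threshold
    labels, n = ndimage.label(low, structure=_STRUCT8)
    if n == 0:
        return BinaryMask(np.zeros(hu.shape, dtype=bool))
    border_labels = set(np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]])))
    sizes = ndimage.sum_labels(low, labels, range(1, n + 1))
    interior = [(sizes[i - 1], i) for i in range(1, n + 1) if i not in border_labels]
    keep = [i for _, i in sorted(interior, reverse=True)[:2]]
    mask = np.isin(labels, keep)
    return BinaryMask(ndimage.binary_fill_holes(mask))
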