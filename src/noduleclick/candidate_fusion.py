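"""Candidate fusion and the TM → fallback switch.

Two concerns live here.  First, anchor-window accounting for the anchor-fixed
detector variant: a conventional region-proposal scan evaluates anchors at
every feature-map position over a pyramid of strides, while the anchor-fixed
variant evaluates only a small odd window (default 3x3) centred on the user's
click in each feature map — 21824 versus 45 positions for the default
512x512 / stride 4-64 configuration.

Second, candidate selection: when a fallback detector proposes several masks
A, B, C, ..., the union U of all pairwise intersections is formed and the
candidate with the maximum overlap |candidate ∩ U| wins.  The shipped default
provider re-runs the TM segmenter at alpha ∈ {1, 2, 3} without the lung
constraint, so the rule is exercisable without any trained network; any
external detector can be plugged in through the same provider contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .calibration import ThresholdCalibration
from .ct_io import BinaryMask, HUImage
from .tm_segmentation import (
    ClickSeed,
    Provenance,
    SegmentationResult,
    dilate,
    erode,
    grow_region,
    remove_noise,
    tm_segment,
)

#: Default anchor configuration reproducing the 21824 / 45 position counts.
DEFAULT_IMAGE_SIZE = (512, 512)
DEFAULT_STRIDES = (4, 8, 16, 32, 64)


@dataclass(frozen=True)
class AnchorConfig:
    image_size: tuple[int, int] = DEFAULT_IMAGE_SIZE
    strides: tuple[int, ...] = DEFAULT_STRIDES
    window: int = 3
    anchors_per_position: int = 1

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.strides) or list(self.strides) != sorted(self.strides):
            raise ValueError("strides must be positive and increasing")
        if self.window % 2 == 0 or self.window < 1:
            raise ValueError("window must be odd")


def count_full_scan_anchors(cfg: AnchorConfig = AnchorConfig()) -> int:
    """Anchor positions of a full scan: sum over pyramid levels of
    ceil(rows/stride) * ceil(cols/stride) * anchors_per_position."""
    rows, cols = cfg.image_size
    total = 0
    for s in cfg.strides:
        total += math.ceil(rows / s) * math.ceil(cols / s)
    return total * cfg.anchors_per_position


def count_fixed_anchors(
    cfg: AnchorConfig = AnchorConfig(),
    click: tuple[int, int] | None = None,
) -> int:
    """Anchor positions of the click-fixed variant: a window x window patch in
    each feature map, truncated at feature-map borders.

    With no click given the click is assumed interior, giving
    window^2 * levels * anchors_per_position (45 for the default config).
    """
    half = cfg.window // 2
    if click is None:
        return cfg.window ** 2 * len(cfg.strides) * cfg.anchors_per_position
    rows, cols = cfg.image_size
    total = 0
    for s in cfg.strides:
        fr, fc = math.ceil(rows / s), math.ceil(cols / s)
        r, c = click[0] // s, click[1] // s
        nr = min(fr - 1, r + half) - max(0, r - half) + 1
        nc = min(fc - 1, c + half) - max(0, c - half) + 1
        total += max(0, nr) * max(0, nc)
    return total * cfg.anchors_per_position


@dataclass
class CandidateSet:
    """An ordered list of same-shape candidate masks from a detector."""

    masks: list[BinaryMask] = field(default_factory=list)

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks}
        if len(shapes) > 1:
            raise ValueError(f"candidate masks disagree in shape: {shapes}")

    def __len__(self) -> int:
        return len(self.masks)


def select_candidate(cands: CandidateSet) -> BinaryMask:
    """Pick the candidate with maximum overlap against the union of pairwise
    intersections.

    U is the union of intersections of all distinct candidate pairs; the
    winner maximises |candidate ∩ U|.  Ties break toward the larger candidate,
    then toward earlier list position.  An empty set yields an empty 1x1 mask;
    a singleton is returned unchanged.
    """
    if len(cands) == 0:
        return BinaryMask(np.zeros((1, 1), dtype=bool))
    if len(cands) == 1:
        return cands.masks[0]
    arrays = [m.values for m in cands.masks]
    u = np.zeros_like(arrays[0])
    for i in range(len(arrays)):
        for j in range(i + 1, len(arrays)):
            u |= arrays[i] & arrays[j]
    best = max(
        range(len(arrays)),
        key=lambda i: (int((arrays[i] & u).sum()), int(arrays[i].sum()), -i),
    )
    return cands.masks[best]


#: A provider maps (hu image, click seed) to a CandidateSet.
CandidateProvider = Callable[[HUImage, ClickSeed], CandidateSet]


def multi_alpha_provider(
    calib: ThresholdCalibration,
    alphas: Sequence[float] = (1.0, 2.0, 3.0),
) -> CandidateProvider:
    """Default fallback provider: TM re-run at several alphas, lung-unconstrained.

    Unlike the TM path, the search space is not limited to the lung, which is
    what lets it reach juxtapleural nodules.  Each alpha yields one candidate
    (grow → erode → keep click component → dilate); empty results are dropped.
    """

    def provide(hu: HUImage, seed: ClickSeed) -> CandidateSet:
        everywhere = BinaryMask(np.ones(hu.shape, dtype=bool))
        masks = []
        for a in alphas:
            avg = calib.estimate_avg(seed.start_hu)
            std = calib.estimate_std(seed.start_hu, avg)
            thr = avg - a * std
            grown = grow_region(hu, everywhere, seed, thr)
            if grown.is_empty:
                continue
            eroded = erode(grown)
            if eroded.is_empty:
                continue
            cand = dilate(remove_noise(eroded, seed))
            cand = BinaryMask(cand.values & grown.values)
            if not cand.is_empty:
                masks.append(cand)
        return CandidateSet(masks)

    return provide


def segment_with_fallback(
    hu: HUImage,
    lung: BinaryMask,
    seed: ClickSeed,
    calib: ThresholdCalibration,
    provider: CandidateProvider | None = None,
) -> SegmentationResult:
    """Run TM; on a null result, resolve the provider's candidates instead.

    The fallback mask is deliberately not restricted to the lung mask.  A
    provider failure propagates as an error; a provider returning no usable
    candidate yields a null FALLBACK result.
    """
    result = tm_segment(hu, lung, seed, calib)
    if not result.is_null:
        return result
    if provider is None:
        provider = multi_alpha_provider(calib)
    cands = provider(hu, seed)
    if len(cands) == 0:
        empty = BinaryMask(np.zeros(hu.shape, dtype=bool))
        return SegmentationResult(empty, Provenance.FALLBACK, None, is_null=True)
    chosen = select_candidate(cands)
    if chosen.shape != hu.shape:
        raise ValueError("provider candidates must match the image shape")
    return SegmentationResult(chosen, Provenance.FALLBACK, None, is_null=chosen.is_empty)
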