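"""Synthetic CT phantoms, calibration sets, and imbalanced feature tables.

Everything the segmentation and classification stages consume can be
generated here, bit-reproducibly from a seed, with ground truth attached:

* 2-D chest-like CT slices — air background near −1000 HU, an elliptical
  soft-tissue body near 0 HU, two elliptical lung fields near −800 HU, and
  disc nodules of configurable mean/std HU, optionally juxtapleural (astride
  the lung boundary, which defeats the lung-constrained TM path by design);
* calibration samples (clicked HU, nodule mean, nodule std) drawn from a
  known generating linear model, so regression recovery can be checked
  against the truth;
* imbalanced two-class Gaussian feature tables at a 160:30 majority:minority
  ratio, the regime the ensemble classifier targets.

HU noise is Gaussian per tissue class; no beam hardening or streaks are
simulated — enough to exercise the threshold statistics, not to mimic a
scanner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import DEFAULT_BETA0, DEFAULT_BETA1, CalibrationSample
from .ct_io import BinaryMask, CTSlice, HUImage, to_hounsfield
from .tm_segmentation import ClickSeed

_B, _M = -1024.0, 1.0  # rescale metadata the phantom slices are encoded with


@dataclass(frozen=True)
class NoduleSpec:
    """One disc nodule: (row, col) centre, radius in px, HU mean/std."""

    center: tuple[int, int]
    radius: float = 10.0
    hu_mean: float = -300.0
    hu_std: float = 30.0
    juxtapleural: bool = False

    def __post_init__(self) -> None:
        if self.radius < 2:
            raise ValueError("nodule radius must be >= 2 px")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and tissue statistics of a synthetic CT slice."""

    image_size: tuple[int, int] = (512, 512)
    body_hu: tuple[float, float] = (0.0, 20.0)      # (mean, std)
    lung_hu: tuple[float, float] = (-800.0, 40.0)
    air_hu: tuple[float, float] = (-1000.0, 20.0)
    lung_centers: tuple[tuple[float, float], ...] | None = None
    lung_axes: tuple[tuple[float, float], ...] | None = None
    nodules: tuple[NoduleSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for nod in self.nodules:
            if nod.hu_mean <= self.lung_hu[0]:
                raise ValueError("nodule mean HU must exceed lung mean HU")
            r, c = nod.center
            rows, cols = self.image_size
            if not (0 <= r < rows and 0 <= c < cols):
                raise ValueError(f"nodule centre {nod.center} outside image")

    def resolved_lungs(self):
        rows, cols = self.image_size
        if self.lung_centers is not None and self.lung_axes is not None:
            return self.lung_centers, self.lung_axes
        centers = ((rows * 0.5, cols * 0.32), (rows * 0.5, cols * 0.68))
        axes = ((rows * 0.30, cols * 0.14), (rows * 0.30, cols * 0.14))
        return centers, axes

    @classmethod
    def default(cls, image_size=(512, 512), seed: int = 0,
                juxtapleural: bool = False, radius: float | None = None,
                hu_mean: float = -300.0, hu_std: float = 30.0) -> "PhantomSpec":
        """A single-nodule phantom; juxtapleural places the nodule astride the
        left lung boundary instead of well inside it."""
        rows, cols = image_size
        if radius is None:
            radius = max(4.0, rows / 20)
        cr, cc = rows * 0.5, cols * 0.32           # left lung centre
        ar, ac = rows * 0.30, cols * 0.14
        if juxtapleural:
            # centre just outside the lung wall; the disc straddles the boundary
            center = (int(round(cr)), int(round(cc - ac - 0.4 * radius)))
        else:
            center = (int(round(cr - ar * 0.3)), int(round(cc)))
        nod = NoduleSpec(center=center, radius=radius, hu_mean=hu_mean,
                         hu_std=hu_std, juxtapleural=juxtapleural)
        return cls(image_size=image_size, nodules=(nod,), seed=seed)


def _ellipse_mask(shape, center, axes) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return ((rr - center[0]) / axes[0]) ** 2 + ((cc - center[1]) / axes[1]) ** 2 <= 1.0


def _disc_mask(shape, center, radius) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius ** 2


def make_phantom(
    spec: PhantomSpec, jitter: int = 0
) -> tuple[CTSlice, BinaryMask, BinaryMask, ClickSeed]:
    """Render a phantom: (CT slice, lung mask, nodule truth mask, click seed).

    The click is the truth centroid (jitter shifts it by up to ``jitter`` px
    per axis, for click-robustness tests); the stored values encode the HU
    field under B=−1024, M=1.
    """
    rng = np.random.default_rng(spec.seed)
    rows, cols = spec.image_size
    hu = rng.normal(spec.air_hu[0], spec.air_hu[1], size=(rows, cols))

    body = _ellipse_mask((rows, cols), (rows * 0.5, cols * 0.5),
                         (rows * 0.42, cols * 0.45))
    hu[body] = rng.normal(spec.body_hu[0], spec.body_hu[1], size=int(body.sum()))

    centers, axes = spec.resolved_lungs()
    lung = np.zeros((rows, cols), dtype=bool)
    for ctr, ax in zip(centers, axes):
        lung |= _ellipse_mask((rows, cols), ctr, ax)
    hu[lung] = rng.normal(spec.lung_hu[0], spec.lung_hu[1], size=int(lung.sum()))

    truth = np.zeros((rows, cols), dtype=bool)
    for nod in spec.nodules:
        disc = _disc_mask((rows, cols), nod.center, nod.radius)
        hu[disc] = rng.normal(nod.hu_mean, nod.hu_std, size=int(disc.sum()))
        truth |= disc

    if truth.any():
        r, c = (int(round(v)) for v in np.argwhere(truth).mean(axis=0))
    else:
        r, c = rows // 2, cols // 2
    if jitter:
        r = int(np.clip(r + rng.integers(-jitter, jitter + 1), 0, rows - 1))
        c = int(np.clip(c + rng.integers(-jitter, jitter + 1), 0, cols - 1))

    sv = np.rint((hu - _B) / _M).astype(np.int16)
    ct = CTSlice(sv, rescale_intercept=_B, rescale_slope=_M)
    hu_img = to_hounsfield(ct)
    seed = ClickSeed(row=r, col=c, start_hu=float(hu_img.values[r, c]))
    return ct, BinaryMask(lung), BinaryMask(truth), seed


# ---------------------------------------------------------------------------
# Calibration samples
# ---------------------------------------------------------------------------

#: Generating std-model coefficients of the synthetic calibration population.
DEFAULT_STD_GEN = (32.0, 0.01, 0.01)


def make_calibration_set(
    n: int,
    seed: int | None = None,
    beta: tuple[float, float] = (DEFAULT_BETA0, DEFAULT_BETA1),
    std_gen: tuple[float, float, float] = DEFAULT_STD_GEN,
    noise_avg: float = 5.0,
    noise_std: float = 2.0,
    start_range: tuple[float, float] = (-600.0, 100.0),
) -> tuple[list[CalibrationSample], dict]:
    """Draw n calibration samples from a known generating linear model.

    avg = beta0 + beta1*start + eps,  eps ~ N(0, noise_avg^2);
    std = c0 + c1*start + c2*avg + eta (clipped >= 0), eta ~ N(0, noise_std^2).
    Returns the samples and a metadata dict recording the generating truth.
    """
    if n < 3:
        raise ValueError("need n >= 3")
    rng = np.random.default_rng(seed)
    start = rng.uniform(*start_range, size=n)
    avg = beta[0] + beta[1] * start + rng.normal(0, noise_avg, size=n)
    c0, c1, c2 = std_gen
    std = c0 + c1 * start + c2 * avg + rng.normal(0, noise_std, size=n)
    std = np.clip(std, 0.0, None)
    samples = [CalibrationSample(float(s), float(a), float(d))
               for s, a, d in zip(start, avg, std)]
    meta = {"beta": list(beta), "std_gen": list(std_gen),
            "noise_avg": noise_avg, "noise_std": noise_std, "seed": seed}
    return samples, meta


# ---------------------------------------------------------------------------
# Imbalanced feature tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TableSpec:
    """An imbalanced two-class Gaussian feature table.

    Defaults mirror a 160 invasive (positive, majority) : 30 non-invasive
    (negative, minority) cohort.  Informative features are shifted by
    ±delta/2 between classes; the rest are pure noise.
    """

    n_majority: int = 160
    n_minority: int = 30
    n_features: int = 10
    n_informative: int = 4
    delta: float = 1.6
    sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative > self.n_features:
            raise ValueError("n_informative must be <= n_features")
        if min(self.n_majority, self.n_minority, self.n_features) < 1:
            raise ValueError("counts must be >= 1")


def make_feature_table(spec: TableSpec) -> pd.DataFrame:
    """Generate the table: columns f0..f{p-1} plus a 0/1 ``label`` column.

    Label 1 (positive/invasive) is the majority class; exact requested counts.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_majority + spec.n_minority
    X = rng.normal(0.0, spec.sigma, size=(n, spec.n_features))
    y = np.concatenate([np.ones(spec.n_majority, dtype=int),
                        np.zeros(spec.n_minority, dtype=int)])
    shift = np.where(y[:, None] == 1, spec.delta / 2, -spec.delta / 2)
    X[:, : spec.n_informative] += shift
    order = rng.permutation(n)
    df = pd.DataFrame(X[order], columns=[f"f{j}" for j in range(spec.n_features)])
    df["label"] = y[order]
    return df
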