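"""Adaptive-threshold calibration for click-seeded nodule segmentation.

The segmentation threshold adapts to the clicked pixel through a chain of
three formulas.  From the HU value of the click (``Start``):

    Avg       = beta0 + beta1 * Start            (simple linear regression)
    Std       = c0 + c1 * Start + c2 * Avg       (multiple linear regression)
    Threshold = Avg - alpha * Std

``Avg`` estimates the mean HU of the nodule the user clicked, ``Std`` its HU
standard deviation, and ``alpha`` (default 2) widens the accepted band below
the mean: a larger alpha lowers the threshold and enlarges the segmented area.
Both regressions are ordinary least squares fitted offline on marked nodules;
the reference mean-model coefficients are beta0 = −173.34, beta1 = 0.71.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Reference coefficients of the mean model, fitted on clinically marked nodules.
DEFAULT_BETA0 = -173.34
DEFAULT_BETA1 = 0.71
#: Default weight of the estimated standard deviation in the threshold.
DEFAULT_ALPHA = 2.0

#: Seed of the synthetic calibration set behind the shipped std-model default.
_DEFAULT_STD_SEED = 20231030
_DEFAULT_STD_N = 400


class FitError(ValueError):
    """Raised when a regression design is degenerate (rank-deficient)."""


@dataclass(frozen=True)
class CalibrationSample:
    """One marked nodule: clicked HU, nodule HU mean, nodule HU std."""

    start: float
    avg: float
    std: float

    def __post_init__(self) -> None:
        if self.std < 0:
            raise ValueError("std must be non-negative")


def _as_arrays(samples) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    start = np.asarray([s.start for s in samples], dtype=float)
    avg = np.asarray([s.avg for s in samples], dtype=float)
    std = np.asarray([s.std for s in samples], dtype=float)
    return start, avg, std


def fit_mean_model(samples) -> tuple[float, float]:
    """OLS fit of nodule mean HU on clicked HU; returns (beta0, beta1).

    Requires at least two samples with distinct start values.
    """
    start, avg, _ = _as_arrays(samples)
    if len(start) < 2 or np.ptp(start) == 0:
        raise FitError("need >=2 samples with distinct start values")
    X = np.column_stack([np.ones_like(start), start])
    coef, *_ = np.linalg.lstsq(X, avg, rcond=None)
    return float(coef[0]), float(coef[1])


def fit_std_model(samples) -> tuple[float, float, float]:
    """OLS fit of nodule HU std on (1, start, avg); returns (c0, c1, c2)."""
    start, avg, std = _as_arrays(samples)
    X = np.column_stack([np.ones_like(start), start, avg])
    if len(start) < 3 or np.linalg.matrix_rank(X) < 3:
        raise FitError("need >=3 samples with a non-collinear (start, avg) design")
    coef, *_ = np.linalg.lstsq(X, std, rcond=None)
    return float(coef[0]), float(coef[1]), float(coef[2])


@dataclass
class ThresholdCalibration:
    """The fitted coefficient set driving the adaptive threshold.

    Attributes
    ----------
    beta0, beta1 : mean-model intercept (HU) and slope (unitless).
    std_coeffs : (intercept, coefficient on start, coefficient on avg).
    alpha : non-negative weight of the estimated std in the threshold.
    """

    beta0: float = DEFAULT_BETA0
    beta1: float = DEFAULT_BETA1
    std_coeffs: tuple[float, float, float] = (0.0, 0.0, 0.0)
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        coeffs = [self.beta0, self.beta1, self.alpha, *self.std_coeffs]
        if not np.all(np.isfinite(coeffs)):
            raise ValueError("all calibration coefficients must be finite")
        if self.alpha < 0:
            raise ValueError("alpha must be non-negative")

    # -- fitting -----------------------------------------------------------
    @classmethod
    def fit(cls, samples, alpha: float = DEFAULT_ALPHA) -> "ThresholdCalibration":
        """Fit both regressions on marked-nodule samples."""
        b0, b1 = fit_mean_model(samples)
        c = fit_std_model(samples)
        return cls(beta0=b0, beta1=b1, std_coeffs=c, alpha=alpha)

    @classmethod
    def default(cls, alpha: float = DEFAULT_ALPHA) -> "ThresholdCalibration":
        """Reference mean-model coefficients plus a std model fitted at call
        time on the package's synthetic calibration set (fixed seed)."""
        from .phantom import make_calibration_set

        samples, _ = make_calibration_set(_DEFAULT_STD_N, seed=_DEFAULT_STD_SEED)
        c = fit_std_model(samples)
        return cls(beta0=DEFAULT_BETA0, beta1=DEFAULT_BETA1, std_coeffs=c, alpha=alpha)

    # -- application -------------------------------------------------------
    def estimate_avg(self, start: float) -> float:
        return self.beta0 + self.beta1 * start

    def estimate_std(self, start: float, avg: float) -> float:
        c0, c1, c2 = self.std_coeffs
        # clamp so the threshold can never exceed the estimated mean
        return max(0.0, c0 + c1 * start + c2 * avg)

    def threshold_for(self, start: float) -> float:
        avg = self.estimate_avg(start)
        std = self.estimate_std(start, avg)
        return compute_threshold(avg, std, self.alpha)

    # -- (de)serialisation -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "beta0": self.beta0, "beta1": self.beta1,
            "std_coeffs": list(self.std_coeffs), "alpha": self.alpha,
        }, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ThresholdCalibration":
        d = json.loads(Path(path).read_text())
        return cls(d["beta0"], d["beta1"], tuple(d["std_coeffs"]), d["alpha"])


def estimate_avg(start: float, calib: ThresholdCalibration) -> float:
    """Estimated nodule mean HU for a clicked HU value."""
    return calib.estimate_avg(start)


def estimate_std(start: float, avg: float, calib: ThresholdCalibration) -> float:
    """Estimated nodule HU std; negative predictions clamp to 0."""
    return calib.estimate_std(start, avg)


def compute_threshold(avg: float, std: float, alpha: float) -> float:
    """``Threshold = Avg - alpha * Std``."""
    if std < 0:
        raise ValueError("std must be non-negative")
    return avg - alpha * std


def read_samples_csv(path: str | Path) -> list[CalibrationSample]:
    """Load calibration samples from a CSV with columns start, avg, std."""
    df = pd.read_csv(path)
    return [CalibrationSample(r.start, r.avg, r.std) for r in df.itertuples()]


def write_samples_csv(samples, path: str | Path) -> None:
    pd.DataFrame(
        {"start": [s.start for s in samples],
         "avg": [s.avg for s in samples],
         "std": [s.std for s in samples]}
    ).to_csv(path, index=False)
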