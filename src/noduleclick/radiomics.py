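"""Radiomics-lite feature extraction and filter-based feature ranking.

A compact, fully reproducible feature set for a segmented nodule: 11
first-order HU statistics, 6 shape descriptors, and 4 grey-level
co-occurrence (GLCM) texture features averaged over the four standard 2-D
offsets.  The inventory is deliberately small — the contract under test is
the selection behaviour, not parity with commercial radiomics toolkits.

Ranking supports the four classical filter methods: chi-squared (on features
min-max scaled to [0,1], that ranker only), ANOVA F, information gain with a
single median-split discretisation, and absolute Pearson correlation with the
0/1 label.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skimage.feature import graycomatrix, graycoprops
from skimage.measure import regionprops

from .ct_io import BinaryMask, HUImage

_GLCM_OFFSETS = [(0, 1), (1, 0), (1, 1), (1, -1)]
_GLCM_LEVELS = 32

FEATURE_NAMES: tuple[str, ...] = (
    "hu_mean", "hu_std", "hu_min", "hu_max", "hu_median", "hu_p10", "hu_p90",
    "hu_skewness", "hu_kurtosis", "hu_energy", "hu_entropy",
    "area_px", "perimeter_px", "equivalent_diameter", "eccentricity",
    "solidity", "compactness",
    "glcm_contrast", "glcm_correlation", "glcm_energy", "glcm_homogeneity",
)


def _offset_to_angle(dr: int, dc: int) -> tuple[int, float]:
    # skimage graycomatrix uses (distance, angle); row offset dr maps to -sin.
    angle = np.arctan2(-dr, dc)
    return 1, float(angle)


def _glcm_features(hu: np.ndarray, mask: np.ndarray) -> dict[str, float]:
    """GLCM on a 32-bin quantisation of the masked HU values inside the mask
    bounding box; pixel pairs that leave the mask are excluded."""
    rows, cols = np.nonzero(mask)
    r0, r1, c0, c1 = rows.min(), rows.max(), cols.min(), cols.max()
    patch = hu[r0:r1 + 1, c0:c1 + 1]
    pmask = mask[r0:r1 + 1, c0:c1 + 1]
    vals = patch[pmask]
    lo, hi = vals.min(), vals.max()
    if hi > lo:
        q = np.floor((patch - lo) / (hi - lo) * _GLCM_LEVELS).astype(int)
        q = np.clip(q, 0, _GLCM_LEVELS - 1)
    else:
        q = np.zeros_like(patch, dtype=int)
    # out-of-mask pixels get a sentinel level whose rows/cols are discarded
    q[~pmask] = _GLCM_LEVELS
    dists, angles = zip(*(_offset_to_angle(dr, dc) for dr, dc in _GLCM_OFFSETS))
    glcm = graycomatrix(q.astype(np.uint8), distances=[1], angles=angles,
                        levels=_GLCM_LEVELS + 1, symmetric=True, normed=False)
    glcm = glcm[:_GLCM_LEVELS, :_GLCM_LEVELS, :, :].astype(float)
    sums = glcm.sum(axis=(0, 1), keepdims=True)
    sums[sums == 0] = 1.0
    glcm /= sums
    out = {}
    for prop, name in [("contrast", "glcm_contrast"), ("correlation", "glcm_correlation"),
                       ("energy", "glcm_energy"), ("homogeneity", "glcm_homogeneity")]:
        vals_ = graycoprops(glcm, prop)[0]
        out[name] = float(np.mean(vals_))
    return out


def extract_features(hu: HUImage, mask: BinaryMask) -> dict[str, float]:
    """Compute the full feature vector on the masked pixels of an HU image.

    Deterministic given (image, mask); requires a mask of at least 2 pixels.
    """
    if mask.shape != hu.shape:
        raise ValueError("mask and image shapes differ")
    m = mask.values
    if m.sum() < 2:
        raise ValueError("mask must contain at least 2 pixels")
    v = hu.values[m]

    feats: dict[str, float] = {
        "hu_mean": float(v.mean()),
        "hu_std": float(v.std(ddof=0)),
        "hu_min": float(v.min()),
        "hu_max": float(v.max()),
        "hu_median": float(np.median(v)),
        "hu_p10": float(np.percentile(v, 10)),
        "hu_p90": float(np.percentile(v, 90)),
        "hu_skewness": float(stats.skew(v)) if v.std() > 0 else 0.0,
        "hu_kurtosis": float(stats.kurtosis(v)) if v.std() > 0 else 0.0,
        "hu_energy": float(np.sum(v.astype(float) ** 2)),
    }
    hist, _ = np.histogram(v, bins=_GLCM_LEVELS)
    p = hist / hist.sum()
    p = p[p > 0]
    feats["hu_entropy"] = float(-(p * np.log2(p)).sum())

    props = regionprops(m.astype(np.uint8))[0]
    area = float(props.area)
    perim = float(props.perimeter)
    feats.update({
        "area_px": area,
        "perimeter_px": perim,
        "equivalent_diameter": float(props.equivalent_diameter_area),
        "eccentricity": float(props.eccentricity),
        "solidity": float(props.solidity),
        "compactness": float(4 * np.pi * area / perim ** 2) if perim > 0 else 1.0,
    })
    feats.update(_glcm_features(hu.values, m))
    return feats


@dataclass(frozen=True)
class RankerResult:
    """Per-feature relevance scores from one ranking method (higher = better)."""

    method: str
    scores: dict[str, float]
    degenerate: frozenset[str] = frozenset()

    def ordered(self) -> list[str]:
        # descending score; ties by feature-name order
        return sorted(self.scores, key=lambda f: (-self.scores[f], f))


RANKER_METHODS = ("chi2", "anova_f", "info_gain", "pearson")


def _entropy(labels: np.ndarray) -> float:
    _, counts = np.unique(labels, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log2(p)).sum())


def _info_gain(x: np.ndarray, y: np.ndarray) -> float:
    med = np.median(x)
    left = x <= med
    if left.all() or not left.any():
        return 0.0
    h = _entropy(y)
    n = len(y)
    cond = (left.sum() / n) * _entropy(y[left]) + ((~left).sum() / n) * _entropy(y[~left])
    return h - cond


def rank_features(table: pd.DataFrame, method: str, label_col: str = "label") -> RankerResult:
    """Score every feature column against the binary label.

    Constant features score 0 and are flagged degenerate.  A single-class
    table is an error.
    """
    if method not in RANKER_METHODS:
        raise ValueError(f"method must be one of {RANKER_METHODS}")
    y = table[label_col].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("table must contain both classes")
    feats = [c for c in table.columns if c != label_col]
    X = table[feats].to_numpy(dtype=float)
    const = np.ptp(X, axis=0) == 0

    scores = np.zeros(len(feats))
    ok = ~const
    if ok.any():
        Xo = X[:, ok]
        if method == "chi2":
            from sklearn.feature_selection import chi2 as sk_chi2

            Xs = (Xo - Xo.min(axis=0)) / np.ptp(Xo, axis=0)
            scores[ok], _ = sk_chi2(Xs, y)
        elif method == "anova_f":
            from sklearn.feature_selection import f_classif

            scores[ok], _ = f_classif(Xo, y)
        elif method == "info_gain":
            scores[ok] = [_info_gain(Xo[:, j], y) for j in range(Xo.shape[1])]
        elif method == "pearson":
            yc = y - y.mean()
            Xc = Xo - Xo.mean(axis=0)
            r = (Xc * yc[:, None]).sum(axis=0) / (
                np.sqrt((Xc ** 2).sum(axis=0)) * np.sqrt((yc ** 2).sum())
            )
            scores[ok] = np.abs(r)
    scores = np.nan_to_num(scores, nan=0.0)
    return RankerResult(
        method=method,
        scores=dict(zip(feats, scores.astype(float))),
        degenerate=frozenset(np.asarray(feats)[const]),
    )


def select_top_k(ranks: RankerResult, k: int) -> list[str]:
    """The k highest-scoring feature names; ties resolve by name order."""
    if not 1 <= k <= len(ranks.scores):
        raise ValueError(f"k must be in [1, {len(ranks.scores)}]")
    return ranks.ordered()[:k]


def write_ranking_csv(ranks: RankerResult, path) -> None:
    order = ranks.ordered()
    pd.DataFrame({
        "feature": order,
        "method": ranks.method,
        "score": [ranks.scores[f] for f in order],
        "rank": range(1, len(order) + 1),
    }).to_csv(path, index=False)
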