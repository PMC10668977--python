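import numpy as np
import pytest

from noduleclick import PhantomSpec, ThresholdCalibration, make_phantom, to_hounsfield


@pytest.fixture(scope="session")
def calib():
    """The shipped default calibration (reference mean model + fitted std model)."""
    return ThresholdCalibration.default()


@pytest.fixture(scope="session")
def phantom_case(calib):
    """A small single-nodule phantom with ground truth: (hu, lung, truth, seed)."""
    spec = PhantomSpec.default(image_size=(192, 192), seed=7)
    ct, lung, truth, seed = make_phantom(spec)
    return to_hounsfield(ct), lung, truth, seed


@pytest.fixture(scope="session")
def juxtapleural_case():
    """A phantom whose nodule straddles the lung wall (click outside the lung)."""
    spec = PhantomSpec.default(image_size=(192, 192), seed=11, juxtapleural=True)
    ct, lung, truth, seed = make_phantom(spec)
    return to_hounsfield(ct), lung, truth, seed


def bfs_flood_fill(admissible: np.ndarray, seed_rc: tuple[int, int]) -> np.ndarray:
    """Brute-force 8-connected flood fill, independent of the implementation."""
    from collections import deque

    out = np.zeros_like(admissible, dtype=bool)
    if not admissible[seed_rc]:
        return out
    q = deque([seed_rc])
    out[seed_rc] = True
    rows, cols = admissible.shape
    while q:
        r, c = q.popleft()
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if (dr or dc) and 0 <= rr < rows and 0 <= cc < cols \
                        and admissible[rr, cc] and not out[rr, cc]:
                    out[rr, cc] = True
                    q.append((rr, cc))
    return out


def brute_force_auc(y: np.ndarray, s: np.ndarray) -> float:
    """O(n^2) pairwise concordance with ties counted 1/2."""
    pos = [si for yi, si in zip(y, s) if yi == 1]
    neg = [si for yi, si in zip(y, s) if yi == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))
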