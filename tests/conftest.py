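import numpy as np
import pytest

from fractalmorph import Silhouette
from fractalmorph.reference import ReferenceShapeSpec, make_reference


def brute_force_box_count(mask: np.ndarray, box_size: int, dx: int, dy: int):
    """Independent per-box binning oracle: explicit loops over grid cells.

    The grid is anchored at (-dx, -dy); returns (n_boxes, mu, sigma) over
    occupied boxes with population SD.
    """
    H, W = mask.shape
    masses = []
    y0 = -dy
    while y0 < H:
        x0 = -dx
        while x0 < W:
            sub = mask[max(y0, 0) : y0 + box_size, max(x0, 0) : x0 + box_size]
            m = int(sub.sum())
            if m:
                masses.append(m)
            x0 += box_size
        y0 += box_size
    masses = np.array(masses, dtype=float)
    return len(masses), masses.mean(), masses.std(ddof=0)


def max_pairwise_extent(mask: np.ndarray) -> float:
    """Brute-force Feret diameter over all foreground pixel pairs."""
    pts = np.column_stack(np.nonzero(mask)).astype(float)
    d2 = ((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1)
    return float(np.sqrt(d2.max()))


@pytest.fixture(scope="session")
def std_line() -> Silhouette:
    sil, _ = make_reference(ReferenceShapeSpec("line"))
    return sil


@pytest.fixture(scope="session")
def std_disk() -> Silhouette:
    sil, _ = make_reference(ReferenceShapeSpec("disk"))
    return sil


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
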