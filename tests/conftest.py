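import numpy as np
import pytest
from skimage.draw import disk, polygon

from nervetrack import MaskFrame, SequenceMeta, SimSpec, generate_truth


@pytest.fixture
def meta100():
    return SequenceMeta(px_per_cm=100.0)


@pytest.fixture(scope="session")
def default_truth():
    """One default-parameter synthetic sequence, shared across tests."""
    return generate_truth(SimSpec(seed=7))


def make_disc(radius: float, pad: int = 5) -> np.ndarray:
    n = int(2 * radius) + 2 * pad + 1
    m = np.zeros((n, n), dtype=np.uint8)
    rr, cc = disk((n // 2, n // 2), radius + 0.5)
    m[rr, cc] = 1
    return m


def make_triangle(side: float, pad: int = 20) -> np.ndarray:
    """Filled equilateral triangle, base horizontal, apex down."""
    h = side * np.sqrt(3) / 2
    w = int(side) + 2 * pad
    ht = int(h) + 2 * pad
    rows = np.array([pad, pad, pad + h])
    cols = np.array([pad, pad + side, pad + side / 2])
    m = np.zeros((ht, w), dtype=np.uint8)
    rr, cc = polygon(rows, cols, shape=m.shape)
    m[rr, cc] = 1
    return m


def random_blob(rng: np.random.Generator, size: int = 64) -> np.ndarray:
    """A random single-component blob: union of a few overlapping discs."""
    m = np.zeros((size, size), dtype=np.uint8)
    cy, cx = rng.uniform(size * 0.3, size * 0.7, 2)
    for _ in range(rng.integers(2, 6)):
        r = rng.uniform(4, size * 0.2)
        oy, ox = rng.uniform(-size * 0.12, size * 0.12, 2)
        rr, cc = disk((cy + oy, cx + ox), r, shape=m.shape)
        m[rr, cc] = 1
    return m


def random_mask(rng: np.random.Generator, size: int = 64, p: float = 0.3) -> np.ndarray:
    """A random scatter mask (any number of components, may be empty)."""
    return (rng.random((size, size)) < p).astype(np.uint8)


def frame(pixels, idx: int = 0) -> MaskFrame:
    return MaskFrame(np.asarray(pixels, dtype=np.uint8), frame_index=idx)
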