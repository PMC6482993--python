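import numpy as np
import pytest

from oirquant.image import Image2D


@pytest.fixture
def tiny_image() -> Image2D:
    """2x2 8-bit image [[0, 0], [255, 255]]."""
    return Image2D(np.array([[0, 0], [255, 255]], dtype=np.uint8))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def random_histogram_counts(rng: np.random.Generator) -> np.ndarray:
    """Random 256-bin counts with a random number of occupied bins (>= 2)."""
    counts = np.zeros(256, dtype=np.int64)
    n_occ = int(rng.integers(2, 40))
    bins = rng.choice(256, size=n_occ, replace=False)
    counts[bins] = rng.integers(1, 500, size=n_occ)
    return counts
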