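import numpy as np
import pytest

from macpso import SyntheticSpec, generate, preprocess


@pytest.fixture(scope="session")
def clean_disk():
    """Noise-free disk, 160x160 (radius 40, centered)."""
    return generate(SyntheticSpec(shape="noisy_circle", side_px=160, noise_variance=0.0))


@pytest.fixture(scope="session")
def noisy_disk():
    """The 300x300 disk with additive Gaussian noise, variance 0.04."""
    return generate(SyntheticSpec(shape="noisy_circle", side_px=300, noise_variance=0.04, seed=1))


@pytest.fixture(scope="session")
def cross_image():
    return generate(SyntheticSpec(shape="cross", side_px=256))


@pytest.fixture(scope="session")
def star_image():
    return generate(SyntheticSpec(shape="star", side_px=160, star_points=5))


@pytest.fixture(scope="session")
def clean_disk_dmap(clean_disk):
    """Distance map of the noise-free disk (edge ring at radius ~40)."""
    _, edges, dmap = preprocess(clean_disk.image)
    return edges, dmap


def random_edge_map(rng: np.random.Generator, side: int = 32, n_edges: int = 12) -> np.ndarray:
    """Sparse random binary edge set (at least one edge pixel)."""
    edges = np.zeros((side, side), dtype=np.uint8)
    rows = rng.integers(0, side, n_edges)
    cols = rng.integers(0, side, n_edges)
    edges[rows, cols] = 1
    return edges
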