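import numpy as np
import pytest

from learnedwave.encoding import CoilSensitivities


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def random_coils(n_grid: int, n_coils: int, seed: int = 0) -> CoilSensitivities:
    """Random smooth-ish complex coil maps, RSS-normalized everywhere."""
    r = np.random.default_rng(seed)
    maps = r.standard_normal((n_coils, n_grid, n_grid, n_grid)) + 1j * r.standard_normal(
        (n_coils, n_grid, n_grid, n_grid)
    )
    rss = np.sqrt(np.sum(np.abs(maps) ** 2, axis=0, keepdims=True))
    return CoilSensitivities(maps=maps / rss)


def random_image(n_grid: int, seed: int = 0) -> np.ndarray:
    r = np.random.default_rng(seed)
    return r.standard_normal((n_grid,) * 3) + 1j * r.standard_normal((n_grid,) * 3)


def random_coords(n: int, n_grid: int, seed: int = 0, margin: float = 0.5) -> np.ndarray:
    r = np.random.default_rng(seed)
    half = n_grid / 2 - margin
    return r.uniform(-half, half, size=(n, 3))
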