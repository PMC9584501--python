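import numpy as np
import pytest

from cgcnn.montage import Montage, build_graph, build_spectral_operators
from cgcnn.synthetic import grid_montage


@pytest.fixture
def montage_3x3():
    return grid_montage(3, 3)


@pytest.fixture
def montage_2x3():
    return grid_montage(2, 3)


@pytest.fixture
def ops_2x3(montage_2x3):
    return build_spectral_operators(build_graph(montage_2x3), K=3)


def random_montage(rng, max_side=6, max_n=12) -> Montage:
    """A random subset of a grid, at least two electrodes."""
    rows = rng.integers(2, max_side + 1)
    cols = rng.integers(2, max_side + 1)
    cells = [(r, c) for r in range(rows) for c in range(cols)]
    k = int(rng.integers(2, min(len(cells), max_n) + 1))
    chosen = rng.choice(len(cells), size=k, replace=False)
    picked = [cells[i] for i in chosen]
    return Montage.from_table(
        [f"E{r}_{c}" for r, c in picked],
        [r for r, _ in picked],
        [c for _, c in picked],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
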