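import numpy as np
import pytest

from sece.io import CountMatrix, CoordinateTable, DomainLabeling
from sece.simulate import FixtureSpec, generate_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_counts():
    """5 spots x 4 genes with hand-chosen totals."""
    counts = np.array([
        [100, 100, 50, 0],
        [5, 5, 0, 0],
        [200, 50, 50, 0],
        [10, 9, 0, 0],
        [10, 5, 5, 0],
    ])
    return CountMatrix(counts,
                       [f"s{i}" for i in range(5)],
                       [f"g{j}" for j in range(4)])


@pytest.fixture
def grid_coords():
    """30 points on a 6 x 5 grid."""
    x, y = np.meshgrid(np.arange(6.0), np.arange(5.0))
    pts = np.column_stack([x.ravel(), y.ravel()])
    return CoordinateTable(pts, [f"s{i}" for i in range(len(pts))])


@pytest.fixture(scope="session")
def small_fixture():
    """Deterministic 300-spot, 3-layer NB fixture used across tests."""
    spec = FixtureSpec(n_spots=300, n_genes=80, n_domains=3, effect_size=2.0,
                       family="nb", library_size_range=(200.0, 600.0), seed=7)
    return generate_fixture(spec)


@pytest.fixture
def labeling():
    return DomainLabeling(np.array([0, 1, 0, 2, 1, 2]))
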