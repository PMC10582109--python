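import numpy as np
import pytest

from coexspot.dataset import SpatialExpressionDataset
from coexspot.hotspots import HotspotDetectionConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def grid_dataset(expression: np.ndarray, side: int) -> SpatialExpressionDataset:
    """Wrap a (side*side, n_genes) matrix on a unit-spaced grid."""
    xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    coords = np.column_stack([xs.ravel(), ys.ravel()]).astype(float)
    n, g = expression.shape
    return SpatialExpressionDataset(
        expression=expression,
        coords=coords,
        gene_names=[f"g{i}" for i in range(g)],
        cell_ids=[f"c{i}" for i in range(n)],
    )


@pytest.fixture
def small_random_dataset(rng):
    """50 cells x 20 genes with random coordinates and counts."""
    return SpatialExpressionDataset(
        expression=rng.poisson(2.0, size=(50, 20)).astype(float),
        coords=rng.uniform(0, 100, size=(50, 2)),
        gene_names=[f"g{i}" for i in range(20)],
        cell_ids=[f"c{i}" for i in range(50)],
    )


def planted_two_region_dataset(
    seed: int = 0,
    side: int = 24,
    genes_per_region: int = 10,
    n_noise_genes: int = 10,
    high: float = 5.0,
    low: float = 0.1,
):
    """Two disjoint square regions, each with its own coherent gene set.

    Region A occupies the left third of the grid, region B the right third.
    Expression is Poisson with a strong in-region rate, log1p-transformed.
    Returns (dataset, members_a, members_b).
    """
    rng_ = np.random.default_rng(seed)
    xs, ys = np.meshgrid(np.arange(side), np.arange(side), indexing="ij")
    x = xs.ravel()
    n = side * side
    in_a = x < side // 3
    in_b = x >= side - side // 3
    cols = []
    for region in (in_a, in_b):
        lam = np.where(region, high, low)
        for _ in range(genes_per_region):
            cols.append(rng_.poisson(lam))
    for _ in range(n_noise_genes):
        cols.append(rng_.poisson(low, size=n))
    X = np.log1p(np.column_stack(cols).astype(float))
    d = grid_dataset(X, side)
    d.log_transformed = True
    return d, frozenset(np.nonzero(in_a)[0].tolist()), frozenset(np.nonzero(in_b)[0].tolist())


@pytest.fixture
def two_region_dataset():
    return planted_two_region_dataset(seed=3)


@pytest.fixture
def grid_detection_config():
    """Detection defaults for unit-spaced grid fixtures."""
    return HotspotDetectionConfig(
        epsilon=2.0, local_density=0.2, hotspot_min_size=10, closure=True
    )
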