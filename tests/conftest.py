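import numpy as np
import pytest

from spafac.data import SpatialSample
from spafac.simulate import SimulationSpec, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def tiny_sample(rng):
    """5 genes x 12 spots on a 3x4 grid, moderate Poisson-ish counts."""
    counts = rng.poisson(5.0, size=(5, 12))
    counts[0, 0] += 1  # guard against an all-zero spot
    xs, ys = np.meshgrid(np.arange(4.0), np.arange(3.0))
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    return SpatialSample(sample_id="toy", counts=counts, coords=coords)


@pytest.fixture(scope="session")
def small_two_sample():
    """Small rotated-scenario dataset shared across tests (10x10, 60 genes)."""
    samples, truth = simulate_dataset(
        SimulationSpec(grid_shape=(10, 10), n_genes=60, seed=3))
    return samples, truth
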