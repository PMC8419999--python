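import numpy as np
import pytest

from umires.count_model import CountMatrix
from umires.synthetic_data import SimulationSpec, make_benchmark, simulate_null


@pytest.fixture
def toy() -> CountMatrix:
    return CountMatrix.from_dense([[1, 2], [3, 4]])


@pytest.fixture(scope="session")
def null_sim() -> CountMatrix:
    """Poisson null at the scale used for the slope/variance criteria."""
    return simulate_null(SimulationSpec(n_cells=2000, n_genes=1000, seed=1))


@pytest.fixture(scope="session")
def benchmark_data():
    """Default labeled benchmark: 8 types plus the injected rare population."""
    return make_benchmark(SimulationSpec(n_cells=1, n_genes=2000, seed=7))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)


def random_count_matrix(rng, n_cells, n_genes, lam=2.0) -> CountMatrix:
    counts = rng.poisson(lam, (n_cells, n_genes))
    if counts.sum() == 0:
        counts[0, 0] = 1
    return CountMatrix.from_dense(counts)
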