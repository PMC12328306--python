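import numpy as np
import pytest

from onidsc import ExpressionMatrix, SimulationConfig, simulate_network_expression


@pytest.fixture
def tiny_matrix():
    values = np.array(
        [
            [0.0, 1.0, 2.0],
            [3.0, 0.0, 4.0],
            [5.0, 6.0, 0.0],
        ]
    )
    return ExpressionMatrix(values, ["g1", "g2", "g3"], ["c1", "c2", "c3"])


@pytest.fixture
def planted_dataset():
    """Two planted 1-lag edges among 10 genes, mild noise, no dropout."""
    cfg = SimulationConfig(
        n_cells=200,
        n_genes=10,
        planted_edges=[(0, 1, 0.9, 1), (2, 3, 0.8, 1)],
        marker_gene_count=0,
        noise_sd=0.05,
        seed=11,
    )
    return simulate_network_expression(cfg)


def random_problem(rng, n=None, p=None):
    """A random, well-posed lasso problem for fuzz tests."""
    n = n or int(rng.integers(10, 31))
    p = p or int(rng.integers(1, 9))
    X = rng.normal(size=(n, p)) * rng.uniform(0.5, 2.0, size=p)
    beta = rng.normal(size=p) * (rng.random(p) < 0.6)
    y = X @ beta + rng.normal(scale=rng.uniform(0.05, 1.0), size=n)
    return X, y
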