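import numpy as np
import pytest

import degroot_ga as dg


@pytest.fixture
def rng():
    return np.random.default_rng(20240117)


@pytest.fixture
def full_adjacency_2():
    return dg.AdjacencyMatrix(np.ones((2, 2), dtype=int))


@pytest.fixture
def full_adjacency_3():
    return dg.AdjacencyMatrix(np.ones((3, 3), dtype=int))


@pytest.fixture(scope="session")
def small_dataset():
    """A small recoverable instance: N=4, d=2, T=6, n=30."""
    spec = dg.GeneratorSpec(n_agents=4, mean_degree=2, time_steps=6, bins=30, seed=42)
    return dg.generate_dataset(spec)


@pytest.fixture(scope="session")
def centered_dataset():
    """Like small_dataset but with latent X(0) on bin centres.

    Fitting seeds predictions with the forward-transformed observed initial
    opinions, so a generating matrix is an *exactly* perfect solution only
    when the latent initial opinions already sit on bin centres; this fixture
    provides that case for tests that need a known zero-fitness chromosome.
    """
    n_bins = 30
    scale = dg.OrdinalScale(n_bins)
    rng = np.random.default_rng(99)
    A = dg.generate_network(4, 2, rng)
    W = dg.generate_weight_matrix(A, rng=rng)
    y0 = rng.integers(1, n_bins + 1, size=4)
    x0 = dg.forward_transform(y0, scale)
    latent = dg.degroot_trajectory(W, x0, 6)
    observed = dg.back_transform(latent, scale)
    spec = dg.GeneratorSpec(n_agents=4, mean_degree=2, time_steps=6, bins=n_bins, seed=99)
    return dg.SyntheticDataset(A, W, latent, observed, spec)


def make_weight_matrix(entries, adjacency=None):
    entries = np.asarray(entries, dtype=float)
    if adjacency is None:
        adjacency = dg.AdjacencyMatrix(np.ones(entries.shape, dtype=int))
    return dg.WeightMatrix.from_adjacency(entries, adjacency)
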