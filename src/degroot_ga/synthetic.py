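"""Synthetic data generator for the calibration study's data-generating process.

Each dataset is built in four steps: (1) a connected Erdős–Rényi network of N
agents with edge probability p = d/(N-1), so the expected degree matches the
target mean degree d, redrawn until connected (which also enforces minimum
degree 1), with self-links added; (2) a ground-truth weight matrix whose
self-weights are drawn from a Beta distribution with mean 0.5 and
concentration kappa = alpha + beta = 4 (Beta(2, 2) at defaults) and whose
off-diagonal free weights are Unif(0,1) rescaled to fill the remaining row
mass; (3) latent opinions started at Unif(0,1) and diffused T DeGroot steps;
(4) ordinal observation of every latent opinion on an n-point scale via the
back transformation.

Because all free weights are drawn from continuous interior distributions,
the ground truth almost surely contains no boundary rows — the generating
process is biased against edge-case solutions, which matters when
interpreting parameter-recovery results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network import AdjacencyMatrix, WeightMatrix, degroot_trajectory
from .scale import OrdinalScale, back_transform

__all__ = [
    "GeneratorSpec",
    "SyntheticDataset",
    "generate_network",
    "generate_weight_matrix",
    "generate_dataset",
]

logger = logging.getLogger(__name__)

#: Redraw budget for the connectivity rejection sampler.
MAX_NETWORK_DRAWS = 10_000


@dataclass(frozen=True)
class GeneratorSpec:
    """Study conditions for one synthetic dataset."""

    n_agents: int
    mean_degree: float
    time_steps: int
    bins: int
    seed: int
    self_weight_mean: float = 0.5
    kappa: float = 4.0

    def __post_init__(self) -> None:
        if self.mean_degree < 1:
            raise ValueError("mean_degree must be >= 1")
        if self.mean_degree >= self.n_agents:
            raise ValueError(
                f"mean degree {self.mean_degree} infeasible for N={self.n_agents}"
            )
        if self.time_steps < 2:
            raise ValueError("time_steps must be >= 2")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if not 0.0 < self.self_weight_mean < 1.0:
            raise ValueError("self_weight_mean must lie in (0, 1)")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


@dataclass(frozen=True)
class SyntheticDataset:
    """A generated network, ground truth, latent trajectory, and ordinal panel."""

    adjacency: AdjacencyMatrix
    true_weights: WeightMatrix
    latent: np.ndarray  # (T, N) continuous opinions
    observed: np.ndarray  # (T, N) ordinal opinions in 1..n
    spec: GeneratorSpec


def generate_network(N: int, d: float, rng: np.random.Generator) -> AdjacencyMatrix:
    """Connected Erdős–Rényi network with expected degree d, plus self-links.

    Edges are drawn independently with probability p = d/(N-1); disconnected
    draws are rejected (connectivity implies minimum degree 1).
    """
    if not 1 <= d < N:
        raise ValueError(f"require 1 <= d < N, got d={d}, N={N}")
    p = d / (N - 1)
    for _ in range(MAX_NETWORK_DRAWS):
        upper = rng.random((N, N)) < p
        a = np.zeros((N, N), dtype=np.int8)
        iu = np.triu_indices(N, k=1)
        a[iu] = upper[iu]
        a |= a.T
        g = nx.from_numpy_array(a)
        if nx.is_connected(g):
            np.fill_diagonal(a, 1)
            return AdjacencyMatrix(a)
    raise RuntimeError(
        f"no connected network found in {MAX_NETWORK_DRAWS} draws (N={N}, d={d})"
    )


def generate_weight_matrix(
    A: AdjacencyMatrix,
    self_weight_mean: float = 0.5,
    kappa: float = 4.0,
    rng: np.random.Generator = None,
) -> WeightMatrix:
    """Ground-truth weight matrix: Beta self-weights, rescaled uniform neighbours.

    Self-weight w_ii ~ Beta(kappa*mean, kappa*(1-mean)); each row's neighbour
    weights are Unif(0,1) rescaled to sum to 1 - w_ii.  A row with no
    neighbours gets w_ii = 1 (logged).
    """
    rng = np.random.default_rng() if rng is None else rng
    a = A.entries
    N = A.n_agents
    alpha = kappa * self_weight_mean
    beta = kappa * (1.0 - self_weight_mean)
    w = np.zeros((N, N), dtype=float)
    diag = rng.beta(alpha, beta, size=N)
    for i in range(N):
        nbrs = np.nonzero(a[i] & (np.arange(N) != i))[0]
        if nbrs.size == 0:
            logger.info("agent %d is isolated; self-weight set to 1", i)
            w[i, i] = 1.0
            continue
        w[i, i] = diag[i]
        u = rng.random(nbrs.size)
        w[i, nbrs] = u * ((1.0 - diag[i]) / u.sum())
    return WeightMatrix.from_adjacency(w, A)


def generate_dataset(spec: GeneratorSpec) -> SyntheticDataset:
    """Compose network, weights, latent diffusion, and ordinal observation.

    Fully determined by ``spec`` (including its seed).
    """
    rng = np.random.default_rng(spec.seed)
    A = generate_network(spec.n_agents, spec.mean_degree, rng)
    W = generate_weight_matrix(A, spec.self_weight_mean, spec.kappa, rng)
    x0 = rng.random(spec.n_agents)
    latent = degroot_trajectory(W, x0, spec.time_steps)
    scale = OrdinalScale(spec.bins)
    observed = back_transform(latent, scale)
    return SyntheticDataset(A, W, latent, observed, spec)
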