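"""Social association networks constraining observation and transmission.

Agents sit on a static, unweighted, undirected network; an agent can only
observe (and therefore learn from) the productions of its direct neighbours.
The default architecture is a connected random regular graph so that every
agent has exactly the same number of associates, removing degree variation
as a confound in the acquisition dynamics.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

__all__ = [
    "SocialNetwork",
    "generate_random_regular",
    "generate_ring_lattice",
    "neighbors",
    "to_edge_csv",
    "from_edge_csv",
]


@dataclass(frozen=True)
class SocialNetwork:
    """Unweighted, undirected association network.

    Attributes
    ----------
    adjacency
        ``(N, N)`` binary matrix, symmetric with zero diagonal.
    architecture
        Label of the generator used (``random_regular``, ``ring_lattice``,
        or ``other``).
    degree
        The common degree ``k`` when the network is regular, else ``None``.
    """

    adjacency: np.ndarray
    architecture: str = "other"
    degree: int | None = None

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=np.int8)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError("adjacency must have a zero diagonal")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("edge weights are fixed at 1; entries must be 0/1")
        object.__setattr__(self, "adjacency", adj)

    @property
    def n_agents(self) -> int:
        return self.adjacency.shape[0]

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    def is_connected(self) -> bool:
        return nx.is_connected(nx.from_numpy_array(self.adjacency))

    def mean_shortest_path(self) -> float:
        return nx.average_shortest_path_length(nx.from_numpy_array(self.adjacency))


def generate_random_regular(
    n_agents: int, degree: int, rng_seed: int, max_tries: int = 100
) -> SocialNetwork:
    """Sample a connected ``degree``-regular graph on ``n_agents`` nodes.

    Uses the standard pairing-model sampler and resamples until the graph is
    connected (a disconnected network would stall a purely social diffusion).
    """
    if degree >= n_agents or degree < 1 or (n_agents * degree) % 2 != 0:
        raise ValueError(
            f"no {degree}-regular graph exists on {n_agents} nodes "
            "(need degree < n and n*degree even)"
        )
    rng = np.random.default_rng(rng_seed)
    for _ in range(max_tries):
        g = nx.random_regular_graph(degree, n_agents, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            adj = nx.to_numpy_array(g, nodelist=range(n_agents), dtype=np.int8)
            return SocialNetwork(adj, architecture="random_regular", degree=degree)
    raise RuntimeError("failed to sample a connected regular graph")


def generate_ring_lattice(n_agents: int, degree: int) -> SocialNetwork:
    """Ring lattice: each agent linked to ``degree/2`` neighbours per side."""
    if degree % 2 != 0:
        raise ValueError("ring lattice degree must be even")
    if degree >= n_agents or degree < 2:
        raise ValueError("need 2 <= degree < n_agents")
    g = nx.watts_strogatz_graph(n_agents, degree, p=0.0)
    adj = nx.to_numpy_array(g, nodelist=range(n_agents), dtype=np.int8)
    return SocialNetwork(adj, architecture="ring_lattice", degree=degree)


def neighbors(net: SocialNetwork, agent: int) -> set[int]:
    """Indices j with an edge to ``agent``."""
    if not 0 <= agent < net.n_agents:
        raise IndexError(f"agent index {agent} out of range")
    return set(np.flatnonzero(net.adjacency[agent]).tolist())


def to_edge_csv(net: SocialNetwork, path) -> None:
    """Write the network as an edge list (two 0-based integer columns)."""
    i, j = np.nonzero(np.triu(net.adjacency))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["agent_i", "agent_j"])
        writer.writerows(zip(i.tolist(), j.tolist()))


def from_edge_csv(path, n_agents: int | None = None) -> SocialNetwork:
    """Read an edge-list CSV written by :func:`to_edge_csv`."""
    edges = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        next(reader)  # header
        for row in reader:
            edges.append((int(row[0]), int(row[1])))
    n = n_agents if n_agents is not None else max(max(e) for e in edges) + 1
    adj = np.zeros((n, n), dtype=np.int8)
    for a, b in edges:
        adj[a, b] = adj[b, a] = 1
    return SocialNetwork(adj, architecture="other")
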