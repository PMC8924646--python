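"""Small-world graph metrics with randomized reference networks.

For a binary undirected network we compute the mean clustering coefficient C
and the characteristic path length L, then normalize each by its mean over
degree-preserving randomized reference networks (five by default):
gamma = C/C_rand, lambda = L/L_rand, and the small-world coefficient
sigma = gamma/lambda.  Values of sigma near 1 indicate random-like topology;
sigma > 1 indicates small-world organization, and a decline of sigma toward
1 indicates randomization of the network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .network_construction import Network

__all__ = [
    "NetworkMetrics",
    "clustering_coefficient",
    "characteristic_path_length",
    "degree_preserving_randomization",
    "small_world_metrics",
]


@dataclass(frozen=True)
class NetworkMetrics:
    """C, L and their normalized forms for one subject's network."""

    C: float
    L: float
    gamma: float
    lambda_: float
    sigma: float
    n_nodes: int
    n_edges: int
    n_random_refs: int
    seed: int | None

    def __post_init__(self) -> None:
        if not np.isclose(self.sigma, self.gamma / self.lambda_):
            raise ValueError("sigma must equal gamma/lambda")


def _as_graph(net: Network | nx.Graph) -> nx.Graph:
    if isinstance(net, Network):
        return net.to_networkx()
    return net


def clustering_coefficient(net: Network | nx.Graph) -> float:
    """Mean clustering coefficient over all nodes.

    Per node, the fraction of its neighbours that are themselves connected;
    nodes of degree < 2 contribute 0.
    """
    g = _as_graph(net)
    if g.number_of_nodes() < 1:
        raise ValueError("need at least 1 node")
    return float(nx.average_clustering(g, count_zeros=True))


def characteristic_path_length(net: Network | nx.Graph) -> float:
    """Mean shortest path length over all pairs in the largest component."""
    g = _as_graph(net)
    if g.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    if g.number_of_edges() == 0:
        raise ValueError("path length undefined for an edgeless network")
    if not nx.is_connected(g):
        g = g.subgraph(max(nx.connected_components(g), key=len))
    return float(nx.average_shortest_path_length(g))


def degree_preserving_randomization(
    net: Network | nx.Graph, seed: int | None = None
) -> nx.Graph:
    """Maslov–Sneppen rewiring: 10x|E| attempted double-edge swaps.

    Preserves the degree sequence and edge count exactly.  Graphs that admit
    no legal swap (e.g. complete graphs) are returned unchanged with a
    notice.
    """
    g = _as_graph(net).copy()
    n, m = g.number_of_nodes(), g.number_of_edges()
    if m < 2:
        raise ValueError("need at least 2 edges to randomize")
    if m == n * (n - 1) // 2:
        warnings.warn("complete graph admits no degree-preserving swap", stacklevel=2)
        return g
    nswap = 10 * m
    try:
        nx.double_edge_swap(g, nswap=nswap, max_tries=100 * nswap, seed=seed)
    except nx.NetworkXAlgorithmError as err:  # exhausted tries: keep partial rewiring
        warnings.warn(f"swap budget exhausted: {err}", stacklevel=2)
    return g


def small_world_metrics(
    net: Network | nx.Graph, n_refs: int = 5, seed: int | None = None
) -> NetworkMetrics:
    """Normalized clustering (gamma), path length (lambda) and sigma.

    Reference C and L are averaged over ``n_refs`` independent randomized
    networks first, then used as denominators.  Each reference is seeded as
    ``seed + ref_index`` for reproducibility.
    """
    g = _as_graph(net)
    lcc = max(nx.connected_components(g), key=len) if g.number_of_nodes() else set()
    if len(lcc) < 3:
        raise ValueError("largest connected component must have >= 3 nodes")
    C = clustering_coefficient(g)
    L = characteristic_path_length(g)
    ref_C = np.empty(n_refs)
    ref_L = np.empty(n_refs)
    for i in range(n_refs):
        ref = degree_preserving_randomization(g, seed=None if seed is None else seed + i)
        ref_C[i] = clustering_coefficient(ref)
        ref_L[i] = characteristic_path_length(ref)
    if ref_C.mean() == 0 or ref_L.mean() == 0:
        raise ValueError("reference metrics are zero; normalization undefined")
    gamma = C / ref_C.mean()
    lam = L / ref_L.mean()
    return NetworkMetrics(
        C=C,
        L=L,
        gamma=float(gamma),
        lambda_=float(lam),
        sigma=float(gamma / lam),
        n_nodes=g.number_of_nodes(),
        n_edges=g.number_of_edges(),
        n_random_refs=n_refs,
        seed=seed,
    )
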