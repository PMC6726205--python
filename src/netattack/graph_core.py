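"""Core graph operations shared by every stage of the pipeline.

Graphs are plain :class:`networkx.Graph` objects: simple, undirected, no
self-loops, hashable node identifiers (dense integers ``0..n-1`` after any
file read).  The heavy whole-graph statistics (clustering, average shortest
path) are computed through python-igraph's C core so that 10,000-node
networks are summarised in seconds; results are identical to the
per-pair-BFS definitions, which the test suite verifies on small graphs.
"""

from __future__ import annotations

from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np

__all__ = [
    "NetworkSummary",
    "induced_subgraph",
    "giant_component_fraction",
    "network_summary",
    "to_igraph",
]


@dataclass(frozen=True)
class NetworkSummary:
    """Structural statistics of one network.

    ``avg_local_clustering`` is the Watts–Strogatz average of per-node local
    clustering coefficients, with degree-0 and degree-1 nodes contributing 0.
    ``avg_shortest_path`` is the mean hop distance over all unordered pairs of
    nodes that can reach each other (the only convention that stays finite on
    disconnected graphs).
    """

    n_nodes: int
    n_links: int
    avg_degree: float
    avg_local_clustering: float
    avg_shortest_path: float


def induced_subgraph(g: nx.Graph, keep) -> nx.Graph:
    """Subgraph on ``keep``: those nodes plus every edge with both ends kept.

    Raises ``ValueError`` if ``keep`` contains a node absent from ``g``.
    """
    keep = set(keep)
    unknown = keep - set(g.nodes)
    if unknown:
        raise ValueError(f"nodes not in graph: {sorted(unknown)[:5]}")
    return g.subgraph(keep).copy()


def giant_component_fraction(g: nx.Graph, removed, denominator_n: int) -> float:
    """Size of the largest connected component after deleting ``removed``,
    as a fraction of ``denominator_n`` (the original node count of the true
    network, so curves from partially observed networks stay comparable).
    """
    removed = set(removed)
    unknown = removed - set(g.nodes)
    if unknown:
        raise ValueError(f"nodes not in graph: {sorted(unknown)[:5]}")
    if denominator_n < 1:
        raise ValueError("denominator_n must be >= 1")
    remaining = g.nodes - removed
    if not remaining:
        return 0.0
    sub = g.subgraph(remaining)
    largest = max(len(c) for c in nx.connected_components(sub))
    return largest / denominator_n


def to_igraph(g: nx.Graph) -> tuple[ig.Graph, list]:
    """Convert to an igraph graph; returns (graph, node order used)."""
    nodes = list(g.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    return ig.Graph(n=len(nodes), edges=edges), nodes


def network_summary(g: nx.Graph) -> NetworkSummary:
    """Compute the standard structural statistics of ``g``.

    Raises ``ValueError`` on an empty graph.
    """
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("cannot summarise an empty graph")
    m = g.number_of_edges()
    h, _ = to_igraph(g)
    local = np.array(h.transitivity_local_undirected(mode="zero"), dtype=float)
    # average over reachable unordered pairs; 0.0 when no pair is reachable
    if m == 0:
        apl = 0.0
    else:
        apl = h.average_path_length(directed=False, unconn=True)
    return NetworkSummary(
        n_nodes=n,
        n_links=m,
        avg_degree=2.0 * m / n,
        avg_local_clustering=float(local.mean()),
        avg_shortest_path=float(apl),
    )
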