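"""Network generators and file readers.

Two synthetic families cover the study conditions:

* Barabási–Albert growth, n=10,000 and m=2 by default.  Growth starts from a
  single node and node ``k`` attaches ``min(m, k)`` distinct earlier nodes.
  Attachment probability is proportional to ``degree + 1`` — the shifted-linear
  kernel that is the igraph default ("zero appeal" of 1).  With this convention
  the edge count is exactly ``1 + 2(n-2)`` for m=2 and the average local
  clustering at n=10,000 lands at ≈0.0021.
* Geometric random graphs: n points i.i.d. uniform on the unit square, an edge
  whenever Euclidean distance ≤ radius (0.015 by default).  At the default
  scale a draw holds ≈99.3% of nodes in its giant component but is virtually
  never fully connected, so ``require_connected`` is off by default; it can be
  enabled (with a retry cap) for small graphs.

File readers cover the two real-network formats used in this literature:
GML (e.g. the autonomous-systems graph) and SNAP-style whitespace edge lists
with ``#`` comments (e.g. the Gnutella peer-to-peer graph).  Both coerce the
input to a simple undirected graph with dense integer ids and keep the
original labels in the ``"orig_id"`` node attribute.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from ._util import as_rng

logger = logging.getLogger(__name__)

__all__ = [
    "BAParams",
    "GRGParams",
    "generate_ba",
    "generate_grg",
    "read_gml",
    "read_edge_list",
    "write_edge_list",
]


@dataclass(frozen=True)
class BAParams:
    n: int = 10_000
    m: int = 2
    seed: int | None = None

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.m < 1:
            raise ValueError("m must be >= 1")


@dataclass(frozen=True)
class GRGParams:
    n: int = 10_000
    radius: float = 0.015
    seed: int | None = None
    require_connected: bool = False
    max_retries: int = 100

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not 0.0 <= self.radius <= np.sqrt(2.0):
            raise ValueError("radius must be in [0, sqrt(2)]")


def generate_ba(params: BAParams) -> nx.Graph:
    """Grow a Barabási–Albert network.

    The sampling bag holds each node ``degree + 1`` times, so a draw is
    degree+1-proportional; duplicates within one node's attachment round are
    rejected, keeping the graph simple.
    """
    n, m = params.n, params.m
    rng = as_rng(params.seed)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    bag = [0]  # node 0's zero-appeal entry
    for k in range(1, n):
        quota = min(m, k)
        targets: set[int] = set()
        while len(targets) < quota:
            targets.add(bag[rng.integers(len(bag))])
        for t in targets:
            g.add_edge(k, t)
            bag.append(t)
        bag.append(k)
        bag.extend([k] * quota)
    return g


def _grg_once(n: int, radius: float, rng: np.random.Generator) -> nx.Graph:
    pts = rng.random((n, 2))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    if radius > 0 and n > 1:
        pairs = cKDTree(pts).query_pairs(radius, output_type="ndarray")
        g.add_edges_from(map(tuple, pairs))
    nx.set_node_attributes(g, {i: (float(x), float(y)) for i, (x, y) in enumerate(pts)}, "pos")
    return g


def generate_grg(params: GRGParams) -> nx.Graph:
    """Draw a geometric random graph on the unit square.

    With ``require_connected`` the draw is repeated (fresh coordinates, each
    regeneration logged) until connected, up to ``max_retries``; exceeding the
    cap raises ``RuntimeError`` with the component count of the last draw.
    """
    rng = as_rng(params.seed)
    for attempt in range(params.max_retries + 1):
        g = _grg_once(params.n, params.radius, rng)
        if not params.require_connected or nx.is_connected(g):
            return g
        logger.info(
            "GRG draw %d disconnected (%d components); regenerating",
            attempt + 1,
            nx.number_connected_components(g),
        )
    raise RuntimeError(
        f"no connected GRG in {params.max_retries + 1} draws "
        f"(n={params.n}, radius={params.radius}; last draw had "
        f"{nx.number_connected_components(g)} components)"
    )


def _densify(g: nx.Graph) -> nx.Graph:
    """Relabel nodes to 0..n-1 in sorted-id order (identity for graphs whose
    ids are already dense), keeping the original id as ``orig_id``."""
    mapping = {v: i for i, v in enumerate(sorted(g.nodes))}
    h = nx.relabel_nodes(g, mapping, copy=True)
    nx.set_node_attributes(h, {i: v for v, i in mapping.items()}, "orig_id")
    return h


def read_gml(path) -> nx.Graph:
    """Read a GML file as a simple undirected graph.

    Self-loops and parallel edges are dropped (count logged); directed input
    is symmetrised.  Parse failures propagate from igraph with file context.
    """
    try:
        h = ig.Graph.Read_GML(str(path))
    except Exception as exc:  # igraph raises InternalError with line info
        raise ValueError(f"failed to parse GML file {path}: {exc}") from exc
    n_loops = sum(h.is_loop())
    n_multi = sum(h.is_multiple())
    if n_loops or n_multi:
        logger.warning(
            "%s: dropped %d self-loop(s) and %d duplicate edge(s)", path, n_loops, n_multi
        )
    h.simplify()
    g = nx.Graph()
    g.add_nodes_from(range(h.vcount()))
    g.add_edges_from(h.get_edgelist())
    labels = h.vs["label"] if "label" in h.vs.attributes() else list(range(h.vcount()))
    nx.set_node_attributes(g, dict(enumerate(labels)), "orig_id")
    return g


def read_edge_list(path) -> nx.Graph:
    """Read a SNAP-style whitespace edge list ('#' lines are comments).

    Directed duplicates are collapsed by symmetrisation; self-loops dropped
    with a logged count.  Non-integer tokens raise ``ValueError`` naming the
    offending line.
    """
    g = nx.Graph()
    n_loops = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) not in (1, 2):
                raise ValueError(f"{path}:{lineno}: expected one or two tokens, got {line!r}")
            try:
                ints = [int(t) for t in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer token in {line!r}") from exc
            if len(ints) == 1:  # bare token: isolated node declaration
                g.add_node(ints[0])
                continue
            u, v = ints
            if u == v:
                n_loops += 1
                continue
            g.add_edge(u, v)
    if n_loops:
        logger.warning("%s: dropped %d self-loop(s)", path, n_loops)
    return _densify(g)


def write_edge_list(g: nx.Graph, path) -> None:
    """Write one ``u v`` line per edge, plus a bare ``v`` line per isolated
    node so the node set round-trips with :func:`read_edge_list`."""
    with open(path, "w") as fh:
        for v in g.nodes:
            if g.degree(v) == 0:
                fh.write(f"{v}\n")
        for u, v in g.edges:
            fh.write(f"{u} {v}\n")
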