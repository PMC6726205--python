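"""Link-error model: build the observed network G' from the true network G.

Measurement noise is modelled as two sequential steps on the edge set: a
fraction ``delta`` of true links is deleted uniformly at random, then a
fraction ``alpha`` (of the *original* link count) of false links is added,
drawn uniformly without replacement from node pairs that are non-adjacent
after the deletions.  The node set never changes, so

    |E'| = |E| - round(|E| * delta) + round(|E| * alpha)

holds exactly for every seed.  A false link may re-create a link deleted in
the same call.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from ._util import as_rng, round_half_up

__all__ = ["ErrorParams", "apply_link_errors"]


@dataclass(frozen=True)
class ErrorParams:
    delta: float
    alpha: float
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must be in [0, 1]")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


def _sample_absent_pairs(g: nx.Graph, count: int, rng: np.random.Generator) -> list:
    """Draw ``count`` distinct non-adjacent node pairs uniformly."""
    nodes = sorted(g.nodes)
    n = len(nodes)
    total_pairs = n * (n - 1) // 2
    n_free = total_pairs - g.number_of_edges()
    if count > n_free:
        raise ValueError(
            f"cannot add {count} links: only {n_free} non-adjacent pairs available"
        )
    # rejection sampling is efficient unless the graph is nearly complete
    if count <= n_free // 2:
        chosen: set = set()
        out = []
        while len(out) < count:
            i, j = rng.integers(n), rng.integers(n)
            if i == j:
                continue
            u, v = nodes[i], nodes[j]
            pair = (u, v) if u <= v else (v, u)
            if pair in chosen or g.has_edge(u, v):
                continue
            chosen.add(pair)
            out.append(pair)
        return out
    # dense fallback: enumerate every absent pair and choose without replacement
    absent = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if not g.has_edge(nodes[i], nodes[j])
    ]
    idx = rng.choice(len(absent), size=count, replace=False)
    return [absent[k] for k in idx]


def apply_link_errors(g: nx.Graph, params: ErrorParams) -> nx.Graph:
    """Return the observed network with missing and false links.

    Deletions are drawn first (uniform over the true edge set), additions
    second (uniform over pairs non-adjacent after deletion).  Identical
    (graph, params) inputs yield an identical result.
    """
    n_edges = g.number_of_edges()
    n_del = round_half_up(n_edges * params.delta)
    n_add = round_half_up(n_edges * params.alpha)
    rng = as_rng(params.seed)

    h = g.copy()
    if n_del:
        edges = sorted(tuple(sorted(e)) for e in g.edges)
        idx = rng.choice(n_edges, size=n_del, replace=False)
        h.remove_edges_from(edges[k] for k in idx)
    if n_add:
        h.add_edges_from(_sample_absent_pairs(h, n_add, rng))
    return h
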