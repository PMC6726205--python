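"""Attack strategies: node removal priorities computed on the observed network.

Three strategies are implemented:

* ``Degree`` — static: rank nodes once by their degree in the observed graph.
* ``HDA`` (high-degree adaptive) — repeatedly remove a current-maximum-degree
  node and recompute degrees on the remaining graph.
* ``CI`` (collective influence) — score each node by

      CI_l(i) = (k_i - 1) * sum_{j in dBall(i, l)} (k_j - 1)

  where ``dBall(i, l)`` is the set of nodes at hop distance exactly ``l`` from
  ``i``; used adaptively like HDA.  After a removal only nodes within distance
  ``l + 1`` of the removed node can change score (any ball of radius ``l``
  that contains the removed node, or a neighbor of it on its boundary, has a
  center within ``l + 1`` hops), so recomputation is localized; the result is
  identical to full recomputation, which the test suite verifies against a
  brute-force oracle.

All ties are broken uniformly at random under the supplied seed.  Orders are
always full permutations of the observed node set.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata

from ._util import as_rng

__all__ = [
    "AttackOrder",
    "rank_degree",
    "attack_order_hda",
    "ci_values",
    "attack_order_ci",
    "ranking_with_unobserved",
]


@dataclass(frozen=True)
class AttackOrder:
    """A removal priority over the observed graph's nodes.

    ``order`` is a permutation of the observed node set, highest priority
    first.  ``scores`` holds static per-node scores when the strategy is
    score-based (Degree, static CI); adaptive orders carry no scores.
    """

    strategy: str
    order: tuple
    scores: dict | None = None
    l: int | None = field(default=None)

    def __post_init__(self):
        if self.strategy == "CI" and (self.l is None or self.l < 1):
            raise ValueError("CI requires ball radius l >= 1")

    def to_frame(self) -> pd.DataFrame:
        """Serializable table with columns node_id, rank, score."""
        return pd.DataFrame(
            {
                "node_id": list(self.order),
                "rank": np.arange(1, len(self.order) + 1),
                "score": [self.scores.get(v) if self.scores else None for v in self.order],
            }
        )


def _shuffled_nodes(g: nx.Graph, rng: np.random.Generator) -> list:
    nodes = sorted(g.nodes)
    rng.shuffle(nodes)
    return nodes


def rank_degree(g_obs: nx.Graph, seed=None) -> AttackOrder:
    """Static degree ranking: sort once by observed degree, descending."""
    if g_obs.number_of_nodes() == 0:
        raise ValueError("empty observed graph")
    rng = as_rng(seed)
    nodes = _shuffled_nodes(g_obs, rng)  # random order then stable sort = uniform ties
    order = sorted(nodes, key=lambda v: -g_obs.degree(v))
    return AttackOrder("Degree", tuple(order), scores=dict(g_obs.degree()))


def attack_order_hda(g_obs: nx.Graph, seed=None) -> AttackOrder:
    """High-degree adaptive order via a lazy max-heap over current degrees."""
    if g_obs.number_of_nodes() == 0:
        raise ValueError("empty observed graph")
    rng = as_rng(seed)
    adj = {v: set(g_obs.neighbors(v)) for v in g_obs.nodes}
    deg = {v: len(nb) for v, nb in adj.items()}
    heap = [(-d, rng.random(), v) for v, d in deg.items()]
    heapq.heapify(heap)
    order = []
    removed = set()
    while heap:
        negd, _, v = heapq.heappop(heap)
        if v in removed or -negd != deg[v]:
            continue  # stale entry
        order.append(v)
        removed.add(v)
        for u in adj[v]:
            if u not in removed:
                adj[u].discard(v)
                deg[u] -= 1
                heapq.heappush(heap, (-deg[u], rng.random(), u))
    return AttackOrder("HDA", tuple(order))


def _ball_boundary_sum(adj: dict, deg: dict, i, l: int) -> float:
    """Sum of (k_j - 1) over nodes at hop distance exactly l from i."""
    seen = {i}
    frontier = [i]
    for _ in range(l):
        nxt = []
        for v in frontier:
            for u in adj[v]:
                if u not in seen:
                    seen.add(u)
                    nxt.append(u)
        frontier = nxt
        if not frontier:
            break
    return sum(deg[j] - 1 for j in frontier)


def _ci_one(adj: dict, deg: dict, i, l: int) -> float:
    if deg[i] <= 1:
        return 0.0
    return (deg[i] - 1) * _ball_boundary_sum(adj, deg, i, l)


def ci_values(g_obs: nx.Graph, l: int) -> dict:
    """Collective-influence scores CI_l for every node of the observed graph."""
    if l < 1:
        raise ValueError("l must be >= 1")
    adj = {v: set(g_obs.neighbors(v)) for v in g_obs.nodes}
    deg = {v: len(nb) for v, nb in adj.items()}
    return {v: _ci_one(adj, deg, v, l) for v in g_obs.nodes}


def attack_order_ci(g_obs: nx.Graph, l: int, seed=None) -> AttackOrder:
    """Adaptive collective-influence order.

    Repeatedly removes a current-maximum-CI node (ties uniform) and rescores
    only the nodes within distance ``l + 1`` of the removal.
    """
    if l < 1:
        raise ValueError("l must be >= 1")
    if g_obs.number_of_nodes() == 0:
        raise ValueError("empty observed graph")
    rng = as_rng(seed)
    adj = {v: set(g_obs.neighbors(v)) for v in g_obs.nodes}
    deg = {v: len(nb) for v, nb in adj.items()}
    ci = {v: _ci_one(adj, deg, v, l) for v in adj}
    heap = [(-c, rng.random(), v) for v, c in ci.items()]
    heapq.heapify(heap)
    order = []
    removed = set()
    while heap:
        negc, _, v = heapq.heappop(heap)
        if v in removed or -negc != ci[v]:
            continue
        order.append(v)
        removed.add(v)
        # collect the (l+1)-ball around v before deleting it, then rescore
        affected = set()
        frontier = deque([(v, 0)])
        seen = {v}
        while frontier:
            x, d = frontier.popleft()
            if d == l + 1:
                continue
            for u in adj[x]:
                if u not in seen:
                    seen.add(u)
                    affected.add(u)
                    frontier.append((u, d + 1))
        for u in adj[v]:
            adj[u].discard(v)
            deg[u] -= 1
        adj[v] = set()
        for u in affected:
            ci[u] = _ci_one(adj, deg, u, l)
            heapq.heappush(heap, (-ci[u], rng.random(), u))
    return AttackOrder("CI", tuple(order), l=l)


def ranking_with_unobserved(order_or_scores: AttackOrder, full_nodes) -> pd.Series:
    """Rank vector over the true node set, unobserved nodes tied at the bottom.

    Observed nodes are ranked by score (rank 1 = best, ties get the average
    rank); every node absent from the observed graph shares the lowest
    (averaged) rank.  When the attack order carries no static scores the
    removal position is used (earlier removal = better).
    """
    full_nodes = sorted(full_nodes)
    observed = set(order_or_scores.order)
    if not observed <= set(full_nodes):
        raise ValueError("observed nodes must be a subset of full_nodes")
    if order_or_scores.scores is not None:
        score = {v: order_or_scores.scores[v] for v in observed}
    else:
        npos = len(order_or_scores.order)
        score = {v: float(npos - i) for i, v in enumerate(order_or_scores.order)}
    values = np.array(
        [score[v] if v in observed else -np.inf for v in full_nodes], dtype=float
    )
    ranks = rankdata(-values, method="average")
    return pd.Series(ranks, index=full_nodes)
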