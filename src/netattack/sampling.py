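"""Node-sampling models: the crawler's partial view of a large network.

Four samplers select ``round(p_s * |V|)`` nodes; the observed network is the
induced subgraph on that set (sampling a node reveals only the links among
sampled nodes).

* ``BFS`` / ``DFS`` — traversal from a uniformly chosen start node with the
  neighbor visit order randomised; when the frontier empties before the quota
  is reached the crawl restarts from a new uniform unvisited node.
* ``SEC`` (sample edge count) — greedy crawler that repeatedly adds the
  candidate node (an unsampled neighbor of the current sample) with the most
  edges into the current sample, ties broken uniformly; restarts like BFS.
* ``RAND`` — uniform without replacement.

BFS, DFS and SEC are degree-biased: hubs are reached early, which is exactly
why attack strategies computed on their samples degrade less than on uniform
samples.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import networkx as nx

from ._util import as_rng, round_half_up
from .graph_core import induced_subgraph

__all__ = ["SampleSpec", "SampleResult", "sample_nodes", "sample_nodes_with_info", "build_observed_network"]

_METHODS = ("BFS", "DFS", "SEC", "RAND")


@dataclass(frozen=True)
class SampleSpec:
    method: str
    p_s: float
    seed: int | None = None

    def __post_init__(self):
        if self.method.upper() not in _METHODS:
            raise ValueError(f"method must be one of {_METHODS}, got {self.method!r}")
        if not 0.0 < self.p_s <= 1.0:
            raise ValueError("p_s must be in (0, 1]")


@dataclass(frozen=True)
class SampleResult:
    nodes: frozenset
    n_restarts: int  # 0 means the sample grew as one connected crawl


def _bfs_sample(g, quota, rng):
    nodes = sorted(g.nodes)
    visited: set = set()
    queue: deque = deque()
    restarts = -1
    while len(visited) < quota:
        if not queue:
            restarts += 1
            unvisited = [v for v in nodes if v not in visited]
            start = unvisited[rng.integers(len(unvisited))]
            visited.add(start)
            queue.append(start)
            continue
        v = queue.popleft()
        nbrs = [u for u in g.neighbors(v) if u not in visited]
        rng.shuffle(nbrs)
        for u in nbrs:
            if len(visited) >= quota:
                break
            visited.add(u)  # mark on enqueue: no duplicates in the queue
            queue.append(u)
    return visited, max(restarts, 0)


def _dfs_sample(g, quota, rng):
    nodes = sorted(g.nodes)
    visited: set = set()
    stack: list = []
    restarts = -1
    while len(visited) < quota:
        if not stack:
            restarts += 1
            unvisited = [v for v in nodes if v not in visited]
            stack.append(unvisited[rng.integers(len(unvisited))])
        v = stack.pop()
        if v in visited:
            continue
        visited.add(v)  # mark on pop: true depth-first visit order
        nbrs = [u for u in g.neighbors(v) if u not in visited]
        rng.shuffle(nbrs)
        stack.extend(nbrs)
    return visited, max(restarts, 0)


def _sec_sample(g, quota, rng):
    nodes = sorted(g.nodes)
    sampled: set = set()
    # edges from each candidate into the current sample
    ties_into_sample: dict = {}
    restarts = -1
    while len(sampled) < quota:
        if not ties_into_sample:
            restarts += 1
            unsampled = [v for v in nodes if v not in sampled]
            pick = unsampled[rng.integers(len(unsampled))]
        else:
            best = max(ties_into_sample.values())
            pool = sorted(v for v, c in ties_into_sample.items() if c == best)
            pick = pool[rng.integers(len(pool))]
            del ties_into_sample[pick]
        sampled.add(pick)
        for u in g.neighbors(pick):
            if u not in sampled:
                ties_into_sample[u] = ties_into_sample.get(u, 0) + 1
    return sampled, max(restarts, 0)


def sample_nodes_with_info(g: nx.Graph, spec: SampleSpec) -> SampleResult:
    """Sample nodes and report how many crawl restarts were needed."""
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("cannot sample from an empty graph")
    quota = round_half_up(spec.p_s * n)
    if quota == 0:
        raise ValueError(f"p_s={spec.p_s} selects zero of {n} nodes")
    rng = as_rng(spec.seed)
    method = spec.method.upper()
    if method == "RAND":
        nodes = sorted(g.nodes)
        idx = rng.choice(n, size=quota, replace=False)
        return SampleResult(frozenset(nodes[i] for i in idx), 0)
    if method == "SEC":
        sampled, restarts = _sec_sample(g, quota, rng)
    elif method == "DFS":
        sampled, restarts = _dfs_sample(g, quota, rng)
    else:
        sampled, restarts = _bfs_sample(g, quota, rng)
    return SampleResult(frozenset(sampled), restarts)


def sample_nodes(g: nx.Graph, spec: SampleSpec) -> frozenset:
    """Sampled node set of size ``round(p_s * |V|)``."""
    return sample_nodes_with_info(g, spec).nodes


def build_observed_network(g: nx.Graph, sampled) -> nx.Graph:
    """Observed network: the induced subgraph on the sampled nodes."""
    return induced_subgraph(g, sampled)
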