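"""Evaluation of attack orders against the *true* network.

The attacker picks nodes on the observed network G', but damage is always
measured on the true network G: for each removal fraction ``p`` the top
``round(p * |V_true|)`` nodes of the order are removed from G and the giant
component fraction (relative to the original |V_true|) is recorded.  When the
order covers fewer nodes than requested — a sampled observed network cannot
name unsampled nodes — the removal count is capped at the order length, so
curves plateau beyond the sample size.

Node-ranking similarity between true and observed views is measured with
Spearman's rank correlation on full-length rank vectors (unobserved nodes
tied at the bottom; see :func:`netattack.attack.ranking_with_unobserved`).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._util import round_half_up
from .attack import AttackOrder

__all__ = [
    "GcCurve",
    "default_p_grid",
    "gc_curve",
    "aggregate_gc_curves",
    "curve_area",
    "spearman_rank_correlation",
]


def default_p_grid() -> np.ndarray:
    """Removal fractions 0.00, 0.02, ..., 0.50."""
    return np.round(np.arange(0, 26) * 0.02, 10)


@dataclass(frozen=True)
class GcCurve:
    """Mean giant-component fragmentation curve over replicates."""

    p_grid: np.ndarray
    mean_gc: np.ndarray
    sd_gc: np.ndarray
    n_replicates: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"p": self.p_grid, "mean_gc": self.mean_gc, "sd_gc": self.sd_gc}
        )


def gc_curve(g_true: nx.Graph, order: AttackOrder, p_grid=None) -> np.ndarray:
    """One replicate: GC fraction of the true network at each removal fraction.

    Removed nodes are counted and the surviving graph's components recomputed
    incrementally (union-find over nodes added back in reverse order), so one
    full curve costs O((n + m) * alpha) rather than one component sweep per
    grid point.
    """
    if p_grid is None:
        p_grid = default_p_grid()
    p_grid = np.asarray(p_grid, dtype=float)
    nodes = set(g_true.nodes)
    if not set(order.order) <= nodes:
        raise ValueError("attack order names nodes absent from the true network")
    n_true = g_true.number_of_nodes()
    counts = [min(round_half_up(p * n_true), len(order.order)) for p in p_grid]

    # reverse union-find: start from the fully attacked graph, add nodes back
    max_removed = max(counts)
    survivors = [v for v in g_true.nodes if v not in set(order.order[:max_removed])]
    parent: dict = {}
    size: dict = {}
    best = [0]  # current largest component size, boxed for closure updates

    def find(v):
        root = v
        while parent[root] != root:
            root = parent[root]
        while parent[v] != root:
            parent[v], v = root, parent[v]
        return root

    def add_node(v):
        parent[v] = v
        size[v] = 1
        best[0] = max(best[0], 1)
        for u in g_true.neighbors(v):
            if u in parent:
                ru, rv = find(u), find(v)
                if ru != rv:
                    if size[ru] < size[rv]:
                        ru, rv = rv, ru
                    parent[rv] = ru
                    size[ru] += size[rv]
                    best[0] = max(best[0], size[ru])

    for v in survivors:
        add_node(v)
    fractions = np.empty(len(p_grid))
    # walk the grid from the largest removal count downward, restoring nodes
    by_count = sorted(range(len(p_grid)), key=lambda i: counts[i], reverse=True)
    restored = max_removed
    for i in by_count:
        while restored > counts[i]:
            restored -= 1
            add_node(order.order[restored])
        fractions[i] = best[0] / n_true if parent else 0.0
    return fractions


def aggregate_gc_curves(replicate_curves, p_grid=None) -> GcCurve:
    """Average per-replicate curves into a :class:`GcCurve`."""
    if p_grid is None:
        p_grid = default_p_grid()
    arr = np.asarray(list(replicate_curves), dtype=float)
    if arr.ndim != 2:
        raise ValueError("expected a sequence of per-replicate curves")
    return GcCurve(
        p_grid=np.asarray(p_grid, dtype=float),
        mean_gc=arr.mean(axis=0),
        sd_gc=arr.std(axis=0, ddof=0),
        n_replicates=arr.shape[0],
    )


def curve_area(p_grid, gc_values) -> float:
    """Trapezoidal area under a GC curve — a scalar attack-quality summary
    (smaller = more effective attack)."""
    return float(np.trapezoid(np.asarray(gc_values), np.asarray(p_grid)))


def spearman_rank_correlation(rank_a, rank_b) -> float:
    """Spearman correlation of two rank vectors over the same node universe.

    Inputs are tied-average rank vectors (e.g. from
    :func:`ranking_with_unobserved`); the statistic is their Pearson
    correlation.  If both vectors are constant the correlation is undefined
    and a ``ValueError`` is raised; if exactly one side is constant the
    correlation is 0 by convention.
    """
    a = np.asarray(rank_a, dtype=float)
    b = np.asarray(rank_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("rank vectors must be 1-D, equal length, n >= 2")
    sa, sb = a.std(), b.std()
    if sa == 0 and sb == 0:
        raise ValueError("both rank vectors are constant; correlation undefined")
    if sa == 0 or sb == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])
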