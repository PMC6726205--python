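"""Discrete-time SIR epidemic with an immunized compartment.

States: susceptible (S), infected (I), removed/recovered (R) and immunized
(M).  Immunized nodes take no part in transmission — they can neither infect
nor be infected — but still count in the node total, so the outcome measure

    non_infected_fraction = (final S + M) / |V|

rewards immunization sets that block spread.  Dynamics are a synchronous
probabilistic automaton: at each step every susceptible node is infected
independently with probability ``beta`` per currently infected neighbor,
then every node that was infected at the start of the step recovers with
probability ``gamma`` (so a node can transmit in the step it recovers).
The epidemic starts from one uniformly chosen non-immunized node and stops
when no infected nodes remain, which happens with probability 1 whenever
``gamma > 0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix

from ._util import as_rng, round_half_up
from .attack import AttackOrder

__all__ = ["SIRParams", "SIROutcome", "simulate_sir", "immunization_curve"]


@dataclass(frozen=True)
class SIRParams:
    beta: float = 0.1
    gamma: float = 0.01
    seed: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")


@dataclass(frozen=True)
class SIROutcome:
    final_s: int
    final_r: int
    n_immunized: int

    @property
    def n_nodes(self) -> int:
        return self.final_s + self.final_r + self.n_immunized

    @property
    def non_infected_fraction(self) -> float:
        return (self.final_s + self.n_immunized) / self.n_nodes


class _SIRMachine:
    """Reusable simulator for one (graph, immunized set) pair.

    Builds the adjacency matrix of the non-immunized induced subgraph once so
    repeated runs (the per-configuration replicates) stay cheap.
    """

    def __init__(self, g: nx.Graph, immunized):
        immunized = set(immunized)
        unknown = immunized - set(g.nodes)
        if unknown:
            raise ValueError(f"immunized nodes not in graph: {sorted(unknown)[:5]}")
        self.n_total = g.number_of_nodes()
        self.n_immunized = len(immunized)
        self.active = [v for v in g.nodes if v not in immunized]
        if not self.active:
            raise ValueError("at least one non-immunized node is required")
        index = {v: i for i, v in enumerate(self.active)}
        rows, cols = [], []
        for u, v in g.edges:
            if u in index and v in index:
                rows += [index[u], index[v]]
                cols += [index[v], index[u]]
        n = len(self.active)
        self.adj = csr_matrix(
            (np.ones(len(rows), dtype=np.int8), (rows, cols)), shape=(n, n)
        )

    def run(self, beta, gamma, rng, max_steps=10_000_000) -> SIROutcome:
        n = len(self.active)
        infected = np.zeros(n, dtype=bool)
        susceptible = np.ones(n, dtype=bool)
        infected[rng.integers(n)] = True
        susceptible &= ~infected
        n_recovered = 0
        for _ in range(max_steps):
            if not infected.any():
                break
            n_inf_nbrs = self.adj.dot(infected.astype(np.int8))
            at_risk = susceptible & (n_inf_nbrs > 0)
            p_inf = 1.0 - (1.0 - beta) ** n_inf_nbrs[at_risk]
            newly = np.zeros(n, dtype=bool)
            newly[np.flatnonzero(at_risk)] = rng.random(at_risk.sum()) < p_inf
            recover = infected & (rng.random(n) < gamma)
            infected = (infected & ~recover) | newly
            susceptible &= ~newly
            n_recovered += int(recover.sum())
        else:
            raise RuntimeError(
                f"epidemic did not converge within {max_steps} steps "
                f"({int(infected.sum())} still infected); check gamma > 0"
            )
        return SIROutcome(
            final_s=int(susceptible.sum()),
            final_r=n_recovered,
            n_immunized=self.n_immunized,
        )


def simulate_sir(g_true: nx.Graph, immunized, params: SIRParams, rng=None) -> SIROutcome:
    """Run one epidemic on the true network with the given immunized set."""
    machine = _SIRMachine(g_true, immunized)
    return machine.run(params.beta, params.gamma, as_rng(rng if rng is not None else params.seed))


def immunization_curve(
    g_true: nx.Graph,
    order: AttackOrder,
    p_grid,
    params: SIRParams,
    n_runs: int,
    rng=None,
) -> np.ndarray:
    """Mean non-infected fraction at each immunization fraction ``p``.

    For each ``p`` the top ``min(round(p * |V|), |order|)`` nodes of the
    attack order are immunized and ``n_runs`` independent epidemics are
    averaged.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = as_rng(rng if rng is not None else params.seed)
    n_true = g_true.number_of_nodes()
    out = np.empty(len(list(p_grid)))
    for i, p in enumerate(p_grid):
        k = min(round_half_up(p * n_true), len(order.order))
        machine = _SIRMachine(g_true, order.order[:k])
        runs = [
            machine.run(params.beta, params.gamma, rng).non_infected_fraction
            for _ in range(n_runs)
        ]
        out[i] = float(np.mean(runs))
    return out
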