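"""Factorial experiment runner with disciplined seeding.

One :class:`ExperimentConfig` describes a full grid: a true-network source,
an incompleteness mode (link errors, node sampling, or none), the error or
sampling grids, the attack strategies, the removal/immunization fractions,
and replicate counts.  ``run_experiment`` walks the grid, builds the observed
network for every replicate, computes the attack order on it, evaluates the
giant-component curve (and optionally the SIR immunization curve) on the
true network, and returns one long-format table.

Reproducibility: every stochastic call receives a child generator derived
from ``master_seed`` plus a stable path key — a CRC-32 of the grid-cell label
and the replicate index fed into ``numpy.random.SeedSequence`` — so results
are bit-identical for identical (config, master_seed) regardless of
evaluation order.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Sequence

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import generators
from .attack import AttackOrder, attack_order_ci, attack_order_hda, rank_degree
from .epidemic import SIRParams, immunization_curve
from .evaluation import default_p_grid, gc_curve
from .perturbation import ErrorParams, apply_link_errors
from .sampling import SampleSpec, build_observed_network, sample_nodes

__all__ = ["ExperimentConfig", "run_experiment", "summarize", "child_rng"]

_MODES = ("none", "link_errors", "sampling")
_STRATEGIES = ("degree", "hda", "ci")


def child_rng(master_seed: int, *path) -> np.random.Generator:
    """Child generator for one stochastic call, keyed by a stable path.

    The path elements (strings/numbers) are joined, CRC-32 hashed and mixed
    with the master seed through ``SeedSequence``.
    """
    key = zlib.crc32("/".join(str(x) for x in path).encode())
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), key]))


@dataclass
class ExperimentConfig:
    """Full description of one experiment grid (see module docstring)."""

    network: dict = field(default_factory=lambda: {"kind": "ba", "n": 10_000, "m": 2})
    incompleteness_mode: str = "none"
    error_grid: Sequence[tuple] = ()        # (delta, alpha) pairs
    sample_grid: Sequence[tuple] = ()       # (method, p_s) pairs
    strategies: Sequence[tuple] = (("degree", None),)  # (name, l) pairs
    p_grid: Sequence[float] | None = None
    n_observed_replicates: int = 100
    run_sir: bool = False
    n_sir_runs: int = 1_000
    beta: float = 0.1
    gamma: float = 0.01
    master_seed: int = 0

    def validate(self) -> None:
        if self.incompleteness_mode not in _MODES:
            raise ValueError(f"incompleteness_mode must be one of {_MODES}")
        if self.incompleteness_mode == "link_errors" and not self.error_grid:
            raise ValueError("error_grid is empty for mode link_errors")
        if self.incompleteness_mode == "sampling" and not self.sample_grid:
            raise ValueError("sample_grid is empty for mode sampling")
        if self.n_observed_replicates < 1:
            raise ValueError("n_observed_replicates must be >= 1")
        if self.n_sir_runs < 1:
            raise ValueError("n_sir_runs must be >= 1")
        for name, _l in self.strategies:
            if name.lower() not in _STRATEGIES:
                raise ValueError(f"unknown strategy {name!r} in strategies")
        for p in self.p_grid if self.p_grid is not None else []:
            if not 0.0 <= p <= 1.0:
                raise ValueError("p_grid entries must be in [0, 1]")

    # ---- config file round-trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        d = asdict(self)
        d["error_grid"] = [list(t) for t in self.error_grid]
        d["sample_grid"] = [list(t) for t in self.sample_grid]
        d["strategies"] = [list(t) for t in self.strategies]
        if self.p_grid is not None:
            d["p_grid"] = [float(p) for p in self.p_grid]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for key in ("error_grid", "sample_grid", "strategies"):
            if key in d and d[key] is not None:
                d[key] = [tuple(t) for t in d[key]]
        return cls(**d)


def _load_true_network(spec: dict, rng: np.random.Generator) -> nx.Graph:
    kind = spec.get("kind")
    if kind == "ba":
        params = generators.BAParams(
            n=spec.get("n", 10_000), m=spec.get("m", 2), seed=int(rng.integers(2**31))
        )
        return generators.generate_ba(params)
    if kind == "grg":
        params = generators.GRGParams(
            n=spec.get("n", 10_000),
            radius=spec.get("radius", 0.015),
            seed=int(rng.integers(2**31)),
            require_connected=spec.get("require_connected", False),
        )
        return generators.generate_grg(params)
    if kind == "file":
        path = spec["path"]
        if spec.get("format", "edgelist") == "gml":
            return generators.read_gml(path)
        return generators.read_edge_list(path)
    raise ValueError(f"network.kind must be ba, grg or file, got {kind!r}")


def compute_attack_order(g_obs: nx.Graph, strategy: str, l, seed) -> AttackOrder:
    strategy = strategy.lower()
    if strategy == "degree":
        return rank_degree(g_obs, seed=seed)
    if strategy == "hda":
        return attack_order_hda(g_obs, seed=seed)
    if strategy == "ci":
        return attack_order_ci(g_obs, l=int(l), seed=seed)
    raise ValueError(f"unknown strategy {strategy!r}")


def _observed(g, mode, cell, seed_rng):
    if mode == "none":
        return g
    if mode == "link_errors":
        delta, alpha = cell
        params = ErrorParams(delta=delta, alpha=alpha, seed=int(seed_rng.integers(2**31)))
        return apply_link_errors(g, params)
    method, p_s = cell
    spec = SampleSpec(method=method, p_s=p_s, seed=int(seed_rng.integers(2**31)))
    return build_observed_network(g, sample_nodes(g, spec))


def run_experiment(config: ExperimentConfig) -> pd.DataFrame:
    """Run the full grid and return a long-format result table.

    Columns: mode, delta, alpha, method, p_s, strategy, l, replicate, p,
    gc_fraction and (when ``run_sir``) non_infected_fraction.
    """
    config.validate()
    p_grid = np.asarray(
        config.p_grid if config.p_grid is not None else default_p_grid(), dtype=float
    )
    mode = config.incompleteness_mode
    if mode == "none":
        cells = [None]
    elif mode == "link_errors":
        cells = list(config.error_grid)
    else:
        cells = list(config.sample_grid)

    g_true = _load_true_network(
        config.network, child_rng(config.master_seed, "true_network")
    )
    sir_params = SIRParams(beta=config.beta, gamma=config.gamma)

    records = []
    for cell in cells:
        cell_key = "none" if cell is None else f"{cell[0]}-{cell[1]}"
        for rep in range(config.n_observed_replicates):
            g_obs = _observed(
                g_true, mode, cell, child_rng(config.master_seed, "observe", cell_key, rep)
            )
            for name, l in config.strategies:
                order = compute_attack_order(
                    g_obs,
                    name,
                    l,
                    int(
                        child_rng(
                            config.master_seed, "attack", cell_key, rep, name, l
                        ).integers(2**31)
                    ),
                )
                gc = gc_curve(g_true, order, p_grid)
                sir = None
                if config.run_sir:
                    sir = immunization_curve(
                        g_true,
                        order,
                        p_grid,
                        sir_params,
                        config.n_sir_runs,
                        rng=child_rng(config.master_seed, "sir", cell_key, rep, name, l),
                    )
                for i, p in enumerate(p_grid):
                    rec = {
                        "mode": mode,
                        "delta": cell[0] if mode == "link_errors" else None,
                        "alpha": cell[1] if mode == "link_errors" else None,
                        "method": cell[0] if mode == "sampling" else None,
                        "p_s": cell[1] if mode == "sampling" else None,
                        "strategy": name,
                        "l": l,
                        "replicate": rep,
                        "p": float(p),
                        "gc_fraction": float(gc[i]),
                    }
                    if sir is not None:
                        rec["non_infected_fraction"] = float(sir[i])
                    records.append(rec)
    return pd.DataFrame.from_records(records)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and sd over replicates for every grid cell and fraction p."""
    if table.empty:
        raise ValueError("cannot summarize an empty result table")
    keys = ["mode", "delta", "alpha", "method", "p_s", "strategy", "l", "p"]
    keys = [k for k in keys if k in table.columns]
    values = [c for c in ("gc_fraction", "non_infected_fraction") if c in table.columns]
    out = (
        table.groupby(keys, dropna=False)[values]
        .agg(["mean", "std"])
        .reset_index()
    )
    out.columns = ["_".join(c).rstrip("_") if isinstance(c, tuple) else c for c in out.columns]
    for v in values:  # single replicate: std is NaN, report 0
        col = f"{v}_std"
        if col in out.columns:
            out[col] = out[col].fillna(0.0)
    return out
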