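"""Discrete-time stochastic edge contagion.

Edges are binary: susceptible (0) or percolated (1), with no recovery.  At
each synchronous time step every susceptible edge that shares an endpoint
with at least one percolated edge flips to percolated independently with a
single transmission probability ``p`` (one Bernoulli draw per eligible edge
per step, regardless of how many percolated neighbours it has; a
per-neighbour hazard 1-(1-p)^k is available as an option).

Random draws are consumed in stable edge-index order from one seeded
generator per run, so trajectories are bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .graph import Graph, EdgeStates, as_state_vector

__all__ = ["ContagionConfig", "ContagionTrajectory", "step", "run"]


@dataclass(frozen=True)
class ContagionConfig:
    p: float
    t_max: int
    initial_edges: tuple[int, ...]
    seed: int = 0
    per_neighbor: bool = False  # hazard 1-(1-p)^k instead of flat p

    def __post_init__(self) -> None:
        if not 0.0 <= self.p <= 1.0:
            raise ValueError("transmission probability p must be in [0, 1]")
        if self.t_max < 1:
            raise ValueError("t_max must be >= 1")
        ie = tuple(int(e) for e in self.initial_edges)
        if not ie:
            raise ValueError("initial_edges must be non-empty")
        object.__setattr__(self, "initial_edges", ie)


@dataclass
class ContagionTrajectory:
    """States and tracked diagnostics for steps t = 1 .. t_max."""

    states_by_step: list[np.ndarray]
    infected_count: np.ndarray
    epc_by_step: list[np.ndarray] | None = None
    ebc: np.ndarray | None = None
    ratio_by_step: np.ndarray | None = None

    @property
    def t_max(self) -> int:
        return len(self.states_by_step)


def step(g: Graph, states, p: float, rng: np.random.Generator,
         per_neighbor: bool = False) -> np.ndarray:
    """One synchronous update of binary edge states.

    New infections are decided from the step-start state; draws happen in
    edge-index order for eligible edges only.
    """
    x = as_state_vector(states, g)
    if not np.all((x == 0.0) | (x == 1.0)):
        raise ValueError("simple contagion requires binary edge states")
    new = x.copy()
    for e in range(g.n_edges):
        if x[e] == 1.0:
            continue
        k = sum(1 for f in g.edge_adjacency(e) if x[f] == 1.0)
        if k == 0:
            continue
        prob = 1.0 - (1.0 - p) ** k if per_neighbor else p
        if rng.random() < prob:
            new[e] = 1.0
    return new


def run(g: Graph, cfg: ContagionConfig, track: str = "none") -> ContagionTrajectory:
    """Simulate ``cfg.t_max`` steps from the configured initial edges.

    ``track`` is one of ``none``, ``epc`` or ``epc+ratio``; when tracking,
    EPC (and the EPC/EBC ratio of averages) is recorded at every step.
    """
    if track not in ("none", "epc", "epc+ratio"):
        raise ValueError(f"unknown track mode {track!r}")
    for e in cfg.initial_edges:
        g._check_edge(e)
    rng = np.random.default_rng(cfg.seed)
    x = np.zeros(g.n_edges)
    x[list(cfg.initial_edges)] = 1.0
    states = [x]
    for _ in range(cfg.t_max - 1):
        x = step(g, x, cfg.p, rng, per_neighbor=cfg.per_neighbor)
        states.append(x)
    traj = ContagionTrajectory(
        states_by_step=states,
        infected_count=np.array([int(s.sum()) for s in states]),
    )
    if track != "none":
        from .centrality import edge_betweenness, epc

        ebc = edge_betweenness(g, "normalized").values
        traj.ebc = ebc
        traj.epc_by_step = [epc(g, EdgeStates(s, t=i + 1)).values
                            for i, s in enumerate(states)]
        if track == "epc+ratio":
            denom = ebc.sum()
            traj.ratio_by_step = np.array(
                [v.sum() / denom for v in traj.epc_by_step]
            )
    return traj
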