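"""Diffusive SIR dynamics on a metric graph.

Each vertex v carries classic SIR compartments

    S_v' = -tau_v S_v I_v
    I_v' =  tau_v S_v I_v - eta_v I_v + sum_{e ~ v} alpha_ev I_e(v)
                                       - (sum_{e ~ v} lambda_ev) I_v
    R_v' =  eta_v I_v

while each edge e carries a line density of travelling infected individuals
obeying the diffusion equation  dI_e/dt = d_e d^2I_e/dx^2  on a uniform grid
over the edge's metric length.  The two are coupled at the vertices through
a flux-balance (Kirchhoff-Robin) boundary condition: the diffusive flux into
an edge's endpoint equals injection from the vertex (rate lambda_ev I_v),
minus absorption into the vertex (rate alpha_ev I_e(v)), plus edge-to-edge
transfer at shared vertices (rate nu per ordered edge pair).  Assembled this
way, the total population

    sum_v (S_v + I_v + R_v)  +  sum_e  integral of I_e dx   (trapezoid)

is conserved to machine precision by the explicit Euler scheme used here.

Unpopulated vertices (border crossings, bare junctions) hold no
compartments: they neither inject into nor absorb from their edges, so their
S, I, R stay identically zero; infected density can still pass through them
via the edge-to-edge transfer terms.

Everything is deterministic; there is no randomness in this model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp

from .graph import Graph, EdgeStates

__all__ = [
    "SIRParams",
    "SIRInit",
    "SIRState",
    "MetricSIRProblem",
    "SIRTrajectory",
    "CFLError",
    "SolverDivergence",
    "build_problem",
    "step_sir",
    "run_sir",
    "edge_density_to_state",
    "default_road_params",
    "default_road_init",
]


class CFLError(ValueError):
    """Raised when the explicit diffusion step would be unstable."""


class SolverDivergence(RuntimeError):
    """Raised when a state develops NaNs or blows up."""


@dataclass(frozen=True)
class SIRParams:
    """Model and discretization parameters.

    Rates are per unit time; ``d`` is a diffusion coefficient in
    length^2/time with edge lengths in ~100 km units.  ``lambda_mode`` fixes
    the per-edge departure rate derived from ``lam``: ``"per_degree"`` gives
    ``lam/deg(v)`` per incident edge (total departure ``lam`` regardless of
    degree, the default), ``"per_edge"`` a flat ``lam`` per edge, and
    ``"times_degree"`` ``lam*deg(v)`` per edge.
    """

    tau: float = 0.45          # vertex transmission rate
    eta: float = 0.13          # vertex removal rate
    d: float = 1.5             # edge diffusion coefficient
    lam: float = 0.1           # vertex -> edge departure rate (see lambda_mode)
    lambda_mode: str = "per_degree"
    alpha: float = 0.125       # edge -> vertex absorption rate
    nu: float = 0.1            # edge -> edge transfer rate at a shared vertex
    dt: float = 0.02           # time step
    dx: float = 0.55           # nominal spatial step
    t_end: float = 20.0        # final time (1000 steps at dt=0.02)
    sample_every: int = 10     # store every k-th solver step
    border_mode: str = "reflecting"  # unpopulated vertices: "reflecting" | "absorbing"

    def __post_init__(self) -> None:
        for name in ("tau", "eta", "d", "lam", "alpha", "nu"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dt <= 0 or self.dx <= 0 or self.t_end <= 0:
            raise ValueError("dt, dx and t_end must be positive")
        if self.lambda_mode not in ("per_degree", "per_edge", "times_degree"):
            raise ValueError(f"unknown lambda_mode {self.lambda_mode!r}")
        if self.sample_every < 1:
            raise ValueError("sample_every must be >= 1")
        if self.border_mode not in ("reflecting", "absorbing"):
            raise ValueError(f"unknown border_mode {self.border_mode!r}")


@dataclass(frozen=True)
class SIRInit:
    """Initial condition: which vertices are populated and where the seed is.

    Every populated vertex starts with ``S = s0``; the seed vertex moves
    ``seed_infected`` of it into the infected compartment.  Unpopulated
    vertices start (and stay) at zero.
    """

    populated: frozenset
    seed_vertex: str
    seed_infected: float = 1e-6
    s0: float = 0.25

    def __post_init__(self) -> None:
        object.__setattr__(self, "populated", frozenset(self.populated))
        if self.seed_infected < 0 or self.seed_infected > self.s0:
            raise ValueError("seed_infected must lie in [0, s0]")


@dataclass
class SIRState:
    """Compartments per vertex plus the flat edge-grid density vector."""

    S: np.ndarray
    I: np.ndarray
    R: np.ndarray
    I_grid: np.ndarray
    t: float = 0.0


class MetricSIRProblem:
    """Discretized problem: grids, coupling matrices, initial state.

    The edge dynamics are linear,  dI_grid/dt = A I_grid + B I_vert,  with A
    holding diffusion stencils, absorption losses and edge-to-edge transfer,
    and B the vertex injection.  The vertex ODEs use C (absorption gains)
    and the per-vertex total departure rate ``lam_v``.
    """

    def __init__(self, g: Graph, params: SIRParams, init: SIRInit) -> None:
        if g.lengths is None:
            raise ValueError("metric SIR needs a graph with edge lengths")
        unknown = [v for v in init.populated if v not in g._vindex]
        if unknown:
            raise ValueError(f"populated vertices not in graph: {unknown}")
        if init.seed_vertex not in init.populated:
            raise ValueError("seed vertex must be populated")
        self.g = g
        self.params = params
        self.init = init
        m = g.n_edges
        nv = g.n_vertices

        # per-edge grids
        self.n_pts = np.array(
            [max(3, int(round(l / params.dx)) + 1) for l in g.lengths], dtype=int
        )
        self.dx_e = np.asarray(g.lengths) / (self.n_pts - 1)
        cfl = params.d * params.dt / self.dx_e**2
        bad = np.flatnonzero(cfl > 0.5)
        if bad.size:
            detail = ", ".join(
                f"e{int(e) + 1} (d*dt/dx^2 = {cfl[e]:.3f})" for e in bad
            )
            raise CFLError(f"unstable explicit step on edges: {detail}")
        self.cfl = cfl
        self.offsets = np.concatenate([[0], np.cumsum(self.n_pts)])
        N = int(self.offsets[-1])
        self.n_grid = N
        # trapezoid quadrature weights per grid point
        w = np.zeros(N)
        for e in range(m):
            o, n, h = self.offsets[e], self.n_pts[e], self.dx_e[e]
            w[o:o + n] = h
            w[o] = w[o + n - 1] = h / 2.0
        self.weights = w

        pop = np.array([v in init.populated for v in g.vertices])
        self.populated = pop

        def lam_ev(v: str) -> float:
            deg = g.degree(v)
            if deg == 0:
                return 0.0
            if params.lambda_mode == "per_degree":
                return params.lam / deg
            if params.lambda_mode == "per_edge":
                return params.lam
            return params.lam * deg

        A = sp.lil_matrix((N, N))
        B = sp.lil_matrix((N, nv))
        C = sp.lil_matrix((nv, N))
        lamv = np.zeros(nv)
        # interior diffusion stencils
        for e in range(m):
            o, n, h = self.offsets[e], self.n_pts[e], self.dx_e[e]
            c = params.d / h**2
            for i in range(1, n - 1):
                A[o + i, o + i - 1] += c
                A[o + i, o + i] += -2 * c
                A[o + i, o + i + 1] += c
        # endpoint (vertex) rows: flux balance in a half-cell of width dx_e/2
        gp = {}  # (edge, vertex) -> grid index of that endpoint sample
        for e, (u, v) in enumerate(g.edges):
            gp[(e, u)] = int(self.offsets[e])
            gp[(e, v)] = int(self.offsets[e] + self.n_pts[e] - 1)
        for e, (u, v) in enumerate(g.edges):
            o, n, h = self.offsets[e], self.n_pts[e], self.dx_e[e]
            for vert, p0, p1 in ((u, o, o + 1), (v, o + n - 1, o + n - 2)):
                w0 = h / 2.0
                # diffusive flux into the endpoint half-cell
                A[p0, p1] += params.d / h / w0
                A[p0, p0] += -params.d / h / w0
                vi = g.vertex_index(vert)
                if pop[vi]:
                    le = lam_ev(vert)
                    B[p0, vi] += le / w0
                    lamv[vi] += le
                    A[p0, p0] += -params.alpha / w0
                    C[vi, p0] += params.alpha
                elif params.border_mode == "absorbing":
                    # density crossing an unpopulated boundary vertex leaves
                    # the system (the vertex value is clamped at zero)
                    A[p0, p0] += -params.alpha / w0
                # edge-to-edge transfer with every other incident edge
                for f in g.incident_edges(vert):
                    if f == e:
                        continue
                    A[p0, gp[(f, vert)]] += params.nu / w0
                    A[p0, p0] += -params.nu / w0
        self.A = A.tocsr()
        self.B = B.tocsr()
        self.C = C.tocsr()
        self.lam_v = lamv
        self.grid_point = gp

    # -- state construction ------------------------------------------------

    def initial_state(self) -> SIRState:
        nv = self.g.n_vertices
        S = np.zeros(nv)
        I = np.zeros(nv)
        R = np.zeros(nv)
        S[self.populated] = self.init.s0
        si = self.g.vertex_index(self.init.seed_vertex)
        S[si] = self.init.s0 - self.init.seed_infected
        I[si] = self.init.seed_infected
        return SIRState(S, I, R, np.zeros(self.n_grid), t=0.0)

    def edge_slice(self, e: int) -> slice:
        return slice(int(self.offsets[e]), int(self.offsets[e + 1]))

    def total_mass(self, state: SIRState) -> float:
        return float(state.S.sum() + state.I.sum() + state.R.sum()
                     + self.weights @ state.I_grid)


@dataclass
class SIRTrajectory:
    """Sampled time series of a deterministic run."""

    times: np.ndarray           # (ns,)
    S: np.ndarray               # (ns, |V|)
    I: np.ndarray               # (ns, |V|)
    R: np.ndarray               # (ns, |V|)
    edge_state: np.ndarray      # (ns, |E|) mean density per edge, clipped to [0,1]
    mass: np.ndarray            # (ns,) total population at each sample
    problem: MetricSIRProblem = field(repr=False, default=None)


def build_problem(g: Graph, params: SIRParams, init: SIRInit) -> MetricSIRProblem:
    """Discretize the model on ``g``; raises :class:`CFLError` if unstable."""
    return MetricSIRProblem(g, params, init)


def step_sir(state: SIRState, problem: MetricSIRProblem) -> SIRState:
    """One forward-Euler step of size ``params.dt``."""
    p = problem.params
    S, I, R, Ig = state.S, state.I, state.R, state.I_grid
    react = p.tau * S * I
    dI_grid = problem.A @ Ig + problem.B @ I
    dS = -react
    dI = react - p.eta * I + problem.C @ Ig - problem.lam_v * I
    dR = p.eta * I
    new = SIRState(
        S + p.dt * dS,
        I + p.dt * dI,
        R + p.dt * dR,
        Ig + p.dt * dI_grid,
        t=state.t + p.dt,
    )
    lo = min(new.S.min(initial=0.0), new.I.min(initial=0.0),
             new.I_grid.min(initial=0.0))
    if not (np.isfinite(new.I_grid).all() and np.isfinite(new.I).all()) or lo < -1e-3:
        raise SolverDivergence(f"solver diverged at t = {new.t:.4f}")
    return new


def edge_density_to_state(state: SIRState, problem: MetricSIRProblem) -> EdgeStates:
    """Percolation states: the mean infected density over each edge's grid."""
    m = problem.g.n_edges
    x = np.empty(m)
    for e in range(m):
        x[e] = state.I_grid[problem.edge_slice(e)].mean()
    return EdgeStates(np.clip(x, 0.0, 1.0), t=state.t)


def run_sir(problem: MetricSIRProblem, t_end: float | None = None) -> SIRTrajectory:
    """Integrate to ``t_end`` (default from params), sampling every k steps."""
    p = problem.params
    t_end = p.t_end if t_end is None else t_end
    n_steps = int(round(t_end / p.dt))
    state = problem.initial_state()
    times, Ss, Is, Rs, Es, Ms = [], [], [], [], [], []

    def record(s: SIRState) -> None:
        times.append(s.t)
        Ss.append(s.S.copy())
        Is.append(s.I.copy())
        Rs.append(s.R.copy())
        Es.append(edge_density_to_state(s, problem).x)
        Ms.append(problem.total_mass(s))

    record(state)
    for k in range(1, n_steps + 1):
        state = step_sir(state, problem)
        if k % p.sample_every == 0 or k == n_steps:
            record(state)
    return SIRTrajectory(
        times=np.array(times),
        S=np.vstack(Ss),
        I=np.vstack(Is),
        R=np.vstack(Rs),
        edge_state=np.vstack(Es),
        mass=np.array(Ms),
        problem=problem,
    )


def default_road_params(**overrides) -> SIRParams:
    """The published road-network scenario parameters."""
    return replace(SIRParams(), **overrides) if overrides else SIRParams()


def default_road_init() -> SIRInit:
    """Seed the epidemic at Szczecin (v18) with an infected fraction of 1e-6."""
    from .generators import ROAD_POPULATED

    return SIRInit(populated=ROAD_POPULATED, seed_vertex="v18",
                   seed_infected=1e-6, s0=0.25)
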