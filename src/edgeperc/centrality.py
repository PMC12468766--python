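"""Edge centrality measures for networks undergoing percolation.

Edge betweenness centrality (EBC) scores an edge by the fraction of
all-pairs shortest paths that traverse it.  Edge percolation centrality
(EPC) additionally weighs each shortest path by the percolation state of its
*source edge* — the first edge leaving the path's source vertex — and
normalizes by the total percolation mass outside the focal edge:

    EPC_t(e) = (|E|-1) / (|V| (|V|-1))
               * sum over ordered pairs (a, b), a != b, of
                 [ sum over shortest paths P: a -> b with e in P of x_src(P) ]
                 / sigma_ab
               / ( sum_i x_i  -  x_e )

where ``sigma_ab`` is the number of shortest a-b paths and ``x_src(P)`` the
state of the first edge of P.  When every edge has the same state K > 0 the
source weights and the denominator cancel and EPC reduces edgewise to
normalized EBC.  When a pair is joined by several shortest paths with
different first edges, the pair contributes the average of its paths'
source-edge states (this degenerates to the single-source-edge expression
whenever all its paths share a first edge, and preserves the EBC reduction
exactly).

Edge hop distance (EHD) is the complementary geometric quantity: the minimum
number of hops from an edge's endpoints to any vertex touching an infected
(nonzero-state) edge; 0 for an infected edge itself, infinity if nothing is
infected.

All shortest paths are unweighted (hop-count) paths; metric edge lengths
play no role here.  Path counting uses exact integer/float DAG recursions —
no floating-point distances.
"""

from __future__ import annotations

import time
from collections import deque
from dataclasses import dataclass

import numpy as np

from .graph import Graph, as_state_vector

__all__ = [
    "CentralityScores",
    "edge_betweenness",
    "epc",
    "epc_oracle",
    "ehd",
    "ratio_of_averages",
    "benchmark_epc",
]


@dataclass(frozen=True)
class CentralityScores:
    """Per-edge scores with a measure tag and the time index they refer to."""

    values: np.ndarray
    measure: str  # {"EPC", "EBC_norm", "EBC_raw", "EHD"}
    t: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return self.values.shape[0]

    def __getitem__(self, e: int) -> float:
        return float(self.values[e])


def _brandes_sweep(g: Graph, x: np.ndarray | None):
    """Accumulate ordered-pair shortest-path sums per edge.

    Returns ``(ebc_acc, epc_acc)`` where for each edge e

    * ``ebc_acc[e]  = sum over ordered pairs (a,b) of sigma_ab(e)/sigma_ab``
    * ``epc_acc[e]  = sum over ordered pairs of
      (sum over shortest paths a->b through e of x_src(path)) / sigma_ab``
      (only when ``x`` is given).

    One Brandes dependency sweep per source vertex; the source-edge weight of
    a DAG edge (u, v) is ``x[(source, v)]`` when u is the source itself and
    the path-count-weighted average source state ``sigma_x[u]/sigma[u]``
    otherwise, where ``sigma_x`` satisfies the same predecessor recursion as
    the path counts ``sigma`` but is seeded with the first-edge states.
    """
    n = g.n_vertices
    m = g.n_edges
    ebc_acc = np.zeros(m)
    epc_acc = np.zeros(m) if x is not None else None
    vindex = {v: i for i, v in enumerate(g.vertices)}
    # adjacency as (neighbor index, edge index) lists
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for i, (u, v) in enumerate(g.edges):
        ui, vi = vindex[u], vindex[v]
        adj[ui].append((vi, i))
        adj[vi].append((ui, i))

    for s in range(n):
        dist = np.full(n, -1, dtype=np.int64)
        sigma = np.zeros(n)
        sigma_x = np.zeros(n) if x is not None else None
        preds: list[list[tuple[int, int]]] = [[] for _ in range(n)]
        order: list[int] = []
        dist[s] = 0
        sigma[s] = 1.0
        q = deque([s])
        while q:
            u = q.popleft()
            order.append(u)
            for w, ei in adj[u]:
                if dist[w] < 0:
                    dist[w] = dist[u] + 1
                    q.append(w)
                if dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
                    preds[w].append((u, ei))
                    if x is not None:
                        # seed with the first-edge state at depth 1, then
                        # propagate the summed source-state mass
                        sigma_x[w] += x[ei] if u == s else sigma_x[u]
        delta = np.zeros(n)
        for v in reversed(order):
            for u, ei in preds[v]:
                c = sigma[u] / sigma[v] * (1.0 + delta[v])
                ebc_acc[ei] += c
                if x is not None:
                    f = x[ei] if u == s else sigma_x[u] / sigma[u]
                    epc_acc[ei] += f * c
                delta[u] += c
    return ebc_acc, epc_acc


def edge_betweenness(g: Graph, mode: str = "normalized") -> CentralityScores:
    """Edge betweenness centrality.

    ``normalized`` divides the ordered-pair sum by ``|V| (|V|-1)``;
    ``raw`` reports the unordered-pair sum (for a tree this is the product of
    the component sizes created by deleting the edge).  Disconnected vertex
    pairs contribute nothing.
    """
    if g.n_vertices == 0 or g.n_edges == 0:
        raise ValueError("edge betweenness needs a non-empty graph with edges")
    if mode not in ("normalized", "raw"):
        raise ValueError(f"unknown mode {mode!r}")
    acc, _ = _brandes_sweep(g, None)
    n = g.n_vertices
    if mode == "raw":
        return CentralityScores(acc / 2.0, "EBC_raw")
    return CentralityScores(acc / (n * (n - 1)), "EBC_norm")


def epc(g: Graph, states) -> CentralityScores:
    """Edge percolation centrality at the states' time index.

    Edges for which the percolation mass outside the edge,
    ``sum_i x_i - x_e``, is not positive get an EPC of 0: the measure
    quantifies influence relative to percolation elsewhere in the network,
    and with no mass elsewhere there is nothing to be influential about.
    """
    if g.n_edges < 2:
        raise ValueError("EPC needs at least 2 edges (prefactor |E|-1 degenerate)")
    x = as_state_vector(states, g)
    t = getattr(states, "t", 0.0)
    _, num = _brandes_sweep(g, x)
    n, m = g.n_vertices, g.n_edges
    denom = x.sum() - x
    values = np.zeros(m)
    ok = denom > 0
    values[ok] = (m - 1) / (n * (n - 1)) * num[ok] / denom[ok]
    return CentralityScores(values, "EPC", t=float(t))


def _all_shortest_paths(adj, s, t, dist, n):
    """Yield every shortest path s->t as a list of edge indices (DAG walk)."""
    if s == t or dist[t] < 0:
        return
    stack = [(t, [])]
    while stack:
        v, suffix = stack.pop()
        if v == s:
            yield [ei for _, ei in reversed(suffix)]
            continue
        for u, ei in adj[v]:
            if dist[u] == dist[v] - 1:
                stack.append((u, suffix + [(u, ei)]))


def epc_oracle(g: Graph, states, max_vertices: int = 12) -> CentralityScores:
    """EPC by explicit enumeration of every shortest path of every pair.

    Exponential in the worst case; guarded to small graphs.  Applies the
    defining formula literally, with the same conventions as :func:`epc`
    (ordered pairs, per-pair averaging of source-edge states over multiple
    shortest paths, zero for non-positive outside mass).
    """
    if g.n_vertices > max_vertices:
        raise ValueError(f"oracle limited to |V| <= {max_vertices}")
    if g.n_edges < 2:
        raise ValueError("EPC needs at least 2 edges")
    x = as_state_vector(states, g)
    n, m = g.n_vertices, g.n_edges
    vindex = {v: i for i, v in enumerate(g.vertices)}
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for i, (u, v) in enumerate(g.edges):
        ui, vi = vindex[u], vindex[v]
        adj[ui].append((vi, i))
        adj[vi].append((ui, i))
    num = np.zeros(m)
    for s in range(n):
        # BFS distances from s
        dist = np.full(n, -1, dtype=np.int64)
        dist[s] = 0
        q = deque([s])
        while q:
            u = q.popleft()
            for w, _ in adj[u]:
                if dist[w] < 0:
                    dist[w] = dist[u] + 1
                    q.append(w)
        for t in range(n):
            if t == s or dist[t] < 0:
                continue
            paths = list(_all_shortest_paths(adj, s, t, dist, n))
            sigma = len(paths)
            for path in paths:
                src_state = x[path[0]]
                for ei in set(path):
                    num[ei] += src_state / sigma
    denom = x.sum() - x
    values = np.zeros(m)
    ok = denom > 0
    values[ok] = (m - 1) / (n * (n - 1)) * num[ok] / denom[ok]
    return CentralityScores(values, "EPC", t=float(getattr(states, "t", 0.0)))


def ehd(g: Graph, states) -> CentralityScores:
    """Edge hop distance to the nearest infected edge.

    0 for an edge with a nonzero state; infinity when no edge is infected;
    otherwise the minimum unweighted distance from either endpoint of the
    edge to any vertex incident to a nonzero-state edge.
    """
    x = as_state_vector(states, g)
    m = g.n_edges
    values = np.full(m, np.inf)
    infected = np.flatnonzero(x > 0)
    if infected.size == 0:
        return CentralityScores(values, "EHD", t=float(getattr(states, "t", 0.0)))
    # multi-source BFS from every vertex touching an infected edge
    dist: dict[str, int] = {}
    q = deque()
    for ei in infected:
        for v in g.edges[ei]:
            if v not in dist:
                dist[v] = 0
                q.append(v)
    while q:
        u = q.popleft()
        for w in g.neighbors(u):
            if w not in dist:
                dist[w] = dist[u] + 1
                q.append(w)
    for e in range(m):
        if x[e] > 0:
            values[e] = 0.0
            continue
        u, v = g.edges[e]
        du = dist.get(u, np.inf)
        dv = dist.get(v, np.inf)
        values[e] = min(du, dv)
    return CentralityScores(values, "EHD", t=float(getattr(states, "t", 0.0)))


def ratio_of_averages(g: Graph, states) -> float:
    """Sum of EPC over sum of normalized EBC (equals the ratio of averages).

    Equals 1 exactly when every edge has the same positive state, and tends
    to 1 as a contagion saturates the network.
    """
    ebc_sum = edge_betweenness(g, "normalized").values.sum()
    if ebc_sum <= 0:
        raise ValueError("degenerate graph: total edge betweenness is zero")
    return float(epc(g, states).values.sum() / ebc_sum)


def benchmark_epc(sizes, seed: int, m: int = 1):
    """Time :func:`epc` on scale-free networks of increasing size.

    Returns ``(table, slope)`` where ``table`` is a list of
    ``(|V|, elapsed_seconds)`` rows and ``slope`` the least-squares slope of
    ``log(time)`` against ``log(|V|)``.  The slope characterizes the
    empirical polynomial scaling on the machine at hand; it is reported,
    never asserted.
    """
    sizes = list(sizes)
    if len(sizes) < 2:
        raise ValueError("need at least two sizes to fit a slope")
    if any(b <= a for a, b in zip(sizes, sizes[1:])):
        raise ValueError("sizes must be strictly ascending")
    from .generators import make_scale_free

    rng = np.random.default_rng(seed)
    table = []
    for n in sizes:
        g = make_scale_free(n, seed=int(rng.integers(2**31)), m=m)
        x = rng.uniform(0.0, 1.0, size=g.n_edges)
        t0 = time.perf_counter()
        epc(g, x)
        table.append((n, time.perf_counter() - t0))
    logs = np.log([max(t, 1e-9) for _, t in table])
    logn = np.log([n for n, _ in table])
    slope = float(np.polyfit(logn, logs, 1)[0])
    return table, slope
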