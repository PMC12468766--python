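"""Graph container and edge-list / GraphML I/O.

The central object is :class:`Graph`, a simple undirected network with a
*stable* integer index for every edge.  Stability matters because every other
quantity in this package — percolation states, centrality scores, infection
densities — is a vector indexed by edge, and those vectors must survive a
round trip through files.

Edges may optionally carry positive metric lengths (used by the diffusive SIR
solver) and vertices may carry free-text labels (e.g. city names).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np


class GraphValidationError(ValueError):
    """Raised when a graph or an edge-state vector violates an invariant."""


class ParseError(ValueError):
    """Raised when an input file cannot be parsed; names the offending line."""


@dataclass(frozen=True)
class EdgeStates:
    """Per-edge percolation states ``x_e`` in [0, 1] at a time index ``t``.

    ``x_e = 0`` is a fully susceptible (non-percolated) edge, ``x_e = 1`` a
    fully percolated one; intermediate values describe partial percolation,
    e.g. an infection line-density averaged over a road.
    """

    x: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        x = np.asarray(self.x, dtype=float)
        object.__setattr__(self, "x", x)
        if x.ndim != 1:
            raise GraphValidationError("edge states must be a 1-D vector")
        if np.any(x < 0) or np.any(x > 1):
            raise GraphValidationError("edge states must lie in [0, 1]")

    def __len__(self) -> int:
        return self.x.shape[0]


def as_state_vector(states, g: "Graph") -> np.ndarray:
    """Coerce ``states`` (EdgeStates or array-like) to a validated vector."""
    if isinstance(states, EdgeStates):
        x = states.x
    else:
        x = np.asarray(states, dtype=float)
        if x.ndim != 1 or np.any(x < 0) or np.any(x > 1):
            raise GraphValidationError("edge states must be a 1-D vector in [0, 1]")
    if x.shape[0] != g.n_edges:
        raise GraphValidationError(
            f"state vector length {x.shape[0]} != |E| = {g.n_edges}"
        )
    return x


class Graph:
    """Simple undirected graph with stable edge indices.

    Parameters
    ----------
    edges :
        Iterable of ``(u, v)`` vertex-label pairs.  Edge *k* of the graph is
        the *k*-th pair; this ordering is preserved everywhere.
    vertices :
        Optional explicit vertex ordering (may include isolated vertices).
        Vertices appearing only in ``edges`` are appended in first-seen order.
    lengths :
        Optional per-edge positive metric lengths.
    labels :
        Optional per-vertex annotation (e.g. city name).
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]],
        vertices: Sequence[str] | None = None,
        lengths: Sequence[float] | None = None,
        labels: Mapping[str, str] | None = None,
    ) -> None:
        vs: list[str] = []
        vseen: dict[str, int] = {}
        if vertices is not None:
            for v in vertices:
                v = str(v)
                if v in vseen:
                    raise GraphValidationError(f"duplicate vertex {v!r}")
                vseen[v] = len(vs)
                vs.append(v)
        es: list[tuple[str, str]] = []
        ekeys: set[frozenset] = set()
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                raise GraphValidationError(f"self-loop at vertex {u!r}")
            key = frozenset((u, v))
            if key in ekeys:
                raise GraphValidationError(f"duplicate edge ({u!r}, {v!r})")
            ekeys.add(key)
            for w in (u, v):
                if w not in vseen:
                    vseen[w] = len(vs)
                    vs.append(w)
            es.append((u, v))
        self._vertices: tuple[str, ...] = tuple(vs)
        self._edges: tuple[tuple[str, str], ...] = tuple(es)
        self._vindex = vseen
        self._eindex = {frozenset(e): i for i, e in enumerate(es)}
        if lengths is not None:
            L = np.asarray(list(lengths), dtype=float)
            if L.shape != (len(es),):
                raise GraphValidationError("lengths must have one entry per edge")
            if np.any(L <= 0) or not np.all(np.isfinite(L)):
                raise GraphValidationError("edge lengths must be positive and finite")
            self._lengths = L
        else:
            self._lengths = None
        self.labels: dict[str, str] = dict(labels) if labels else {}
        for v in self.labels:
            if v not in self._vindex:
                raise GraphValidationError(f"label for unknown vertex {v!r}")
        # vertex -> list of (neighbor, edge index), in edge order
        inc: dict[str, list[tuple[str, int]]] = {v: [] for v in vs}
        for i, (u, v) in enumerate(es):
            inc[u].append((v, i))
            inc[v].append((u, i))
        self._incidence = inc

    # -- basic queries -----------------------------------------------------

    @property
    def vertices(self) -> tuple[str, ...]:
        return self._vertices

    @property
    def edges(self) -> tuple[tuple[str, str], ...]:
        return self._edges

    @property
    def lengths(self) -> np.ndarray | None:
        return self._lengths

    @property
    def n_vertices(self) -> int:
        return len(self._vertices)

    @property
    def n_edges(self) -> int:
        return len(self._edges)

    def vertex_index(self, v: str) -> int:
        return self._vindex[v]

    def edge_index(self, u: str, v: str) -> int:
        try:
            return self._eindex[frozenset((u, v))]
        except KeyError:
            raise KeyError(f"no edge ({u!r}, {v!r})") from None

    def has_edge(self, u: str, v: str) -> bool:
        return frozenset((u, v)) in self._eindex

    def degree(self, v: str) -> int:
        return len(self._incidence[v])

    def neighbors(self, v: str) -> list[str]:
        return [w for w, _ in self._incidence[v]]

    def incident_edges(self, v: str) -> list[int]:
        """Edge indices incident to vertex ``v``, in edge order."""
        return [i for _, i in self._incidence[v]]

    def edge_adjacency(self, e: int) -> set[int]:
        """All other edges sharing at least one endpoint with edge ``e``."""
        self._check_edge(e)
        u, v = self._edges[e]
        out = {i for _, i in self._incidence[u]} | {i for _, i in self._incidence[v]}
        out.discard(e)
        return out

    def _check_edge(self, e: int) -> None:
        if not (isinstance(e, (int, np.integer)) and 0 <= e < self.n_edges):
            raise IndexError(f"invalid edge index {e!r} (|E| = {self.n_edges})")

    # -- derived graphs ----------------------------------------------------

    def remove_edge(self, e: int) -> "Graph":
        """Copy of the graph without edge ``e`` (vertex set unchanged).

        Remaining edges keep their relative order; their indices shift down
        by one above ``e``.
        """
        self._check_edge(e)
        edges = [ed for i, ed in enumerate(self._edges) if i != e]
        lengths = None
        if self._lengths is not None:
            lengths = np.delete(self._lengths, e)
        return Graph(edges, vertices=self._vertices, lengths=lengths, labels=self.labels)

    def to_networkx(self):
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(self._vertices)
        for i, (u, v) in enumerate(self._edges):
            attrs = {"index": i}
            if self._lengths is not None:
                attrs["length"] = float(self._lengths[i])
            G.add_edge(u, v, **attrs)
        for v, lab in self.labels.items():
            G.nodes[v]["label"] = lab
        return G

    def is_connected(self) -> bool:
        if self.n_vertices == 0:
            return True
        seen = {self._vertices[0]}
        stack = [self._vertices[0]]
        while stack:
            v = stack.pop()
            for w in self.neighbors(v):
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return len(seen) == self.n_vertices

    def __eq__(self, other) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        if self._vertices != other._vertices or self._edges != other._edges:
            return False
        a, b = self._lengths, other._lengths
        if (a is None) != (b is None):
            return False
        if a is not None and not np.allclose(a, b, rtol=0, atol=0):
            return False
        return True

    def __repr__(self) -> str:
        return f"Graph(|V|={self.n_vertices}, |E|={self.n_edges})"


# -- file I/O ---------------------------------------------------------------


def _sniff_delimiter(line: str, dialect: str | None) -> str | None:
    if dialect == "tsv":
        return "\t"
    if dialect == "csv":
        return ","
    if "\t" in line:
        return "\t"
    if "," in line:
        return ","
    return None  # any whitespace


def read_edge_list(path, dialect: str | None = None):
    """Read a TSV/CSV edge list ``u v [length] [state]``.

    Lines starting with ``#`` and blank lines are ignored.  Returns
    ``(Graph, EdgeStates | None)``; states are returned only when a fourth
    column is present.
    """
    rows: list[list[str]] = []
    linenos: list[int] = []
    delim: str | None = None
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            if delim is None:
                delim = _sniff_delimiter(line, dialect)
            parts = [p.strip() for p in (line.split(delim) if delim else line.split())]
            parts = [p for p in parts if p != ""]
            if len(parts) < 2 or len(parts) > 4:
                raise ParseError(f"{path}:{lineno}: expected 2-4 columns, got {len(parts)}")
            rows.append(parts)
            linenos.append(lineno)
    ncols = {len(r) for r in rows}
    if len(ncols) > 1:
        raise ParseError(f"{path}: inconsistent column counts {sorted(ncols)}")
    edges = [(r[0], r[1]) for r in rows]
    lengths = None
    states = None
    width = ncols.pop() if ncols else 2
    if width >= 3:
        try:
            lengths = [float(r[2]) for r in rows]
        except ValueError as exc:
            raise ParseError(f"{path}: bad length value ({exc})") from None
    try:
        g = Graph(edges, lengths=lengths)
    except GraphValidationError as exc:
        raise GraphValidationError(f"{path}: {exc}") from None
    if width == 4:
        try:
            x = np.array([float(r[3]) for r in rows])
        except ValueError as exc:
            raise ParseError(f"{path}: bad state value ({exc})") from None
        if np.any(x < 0) or np.any(x > 1):
            raise GraphValidationError(f"{path}: edge state outside [0, 1]")
        states = EdgeStates(x)
    return g, states


def write_edge_list(g: Graph, path, states: EdgeStates | None = None, dialect: str = "tsv") -> None:
    """Write ``g`` (and optional states) so that :func:`read_edge_list` round-trips."""
    delim = "\t" if dialect == "tsv" else ","
    x = as_state_vector(states, g) if states is not None else None
    with open(path, "wt", encoding="utf-8") as fh:
        cols = ["u", "v"] + (["length"] if g.lengths is not None else []) + (
            ["state"] if x is not None else []
        )
        fh.write("# " + delim.join(cols) + "\n")
        for i, (u, v) in enumerate(g.edges):
            row = [u, v]
            if g.lengths is not None:
                row.append(repr(float(g.lengths[i])))
            if x is not None:
                row.append(repr(float(x[i])))
            fh.write(delim.join(row) + "\n")


def read_graphml(path):
    """Read a GraphML file; edge attributes ``length``/``state`` are honoured."""
    import networkx as nx

    G = nx.read_graphml(path)
    edges = list(G.edges(data=True))
    if edges and all("index" in d for _, _, d in edges):
        edges.sort(key=lambda t: int(t[2]["index"]))
    lengths = None
    if edges and all("length" in d for _, _, d in edges):
        lengths = [float(d["length"]) for _, _, d in edges]
    g = Graph(
        [(u, v) for u, v, _ in edges],
        vertices=list(G.nodes()),
        lengths=lengths,
        labels={v: d["label"] for v, d in G.nodes(data=True) if "label" in d},
    )
    states = None
    if edges and all("state" in d for _, _, d in edges):
        states = EdgeStates(np.array([float(d["state"]) for _, _, d in edges]))
    return g, states


def write_graphml(g: Graph, path, states: EdgeStates | None = None) -> None:
    G = g.to_networkx()
    if states is not None:
        x = as_state_vector(states, g)
        for i, (u, v) in enumerate(g.edges):
            G.edges[u, v]["state"] = float(x[i])
    import networkx as nx

    nx.write_graphml(G, path)
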