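"""Synthetic and reference network generators.

Four families of networks are used throughout the package:

* an 8-vertex star-and-path tree used to illustrate the centrality measures
  on a graph small enough to check by hand;
* scale-free networks grown by linear preferential attachment, used for
  property tests and runtime benchmarking;
* an 18-vertex / 24-edge metric graph approximating the major roads of
  Poland, with edge lengths in units of ~100 km, used by the diffusive SIR
  solver and the intervention scan;
* tree-like sexual-contact networks (39 vertices, 40 edges by default)
  standing in for the largest component of a gonorrhea outbreak contact
  study, used by the simple contagion simulator.
"""

from __future__ import annotations

import numpy as np

from .graph import Graph

__all__ = [
    "make_synthetic_tree",
    "make_scale_free",
    "make_road_network",
    "make_contact_network",
    "ROAD_INCIDENCE",
    "ROAD_LENGTHS",
    "ROAD_LABELS",
    "ROAD_POPULATED",
]


def make_synthetic_tree() -> Graph:
    """8-vertex synthetic tree: a star at v4 joined by a path to a fork at v6.

    Edges are indexed e1..e7 (0-based 0..6).  Deleting e4=(v4,v5) splits the
    tree into components of sizes 4 and 4 (16 vertex pairs separated);
    deleting e5=(v5,v6) gives 5 and 3 (15 pairs) — the raw edge-betweenness
    values used as a hand-checkable reference.
    """
    edges = [
        ("v1", "v4"),  # e1
        ("v2", "v4"),  # e2
        ("v3", "v4"),  # e3
        ("v4", "v5"),  # e4
        ("v5", "v6"),  # e5
        ("v6", "v7"),  # e6
        ("v6", "v8"),  # e7
    ]
    return Graph(edges)


def make_scale_free(n: int, seed: int, m: int = 1) -> Graph:
    """Connected scale-free network via linear preferential attachment.

    Each arriving vertex attaches ``m`` edges (default 1, i.e. a random
    recursive tree with preferential attachment — the sparsest connected
    case).  Deterministic under a fixed ``seed``.
    """
    if n < 2:
        raise ValueError("need at least 2 vertices")
    import networkx as nx

    G = nx.barabasi_albert_graph(n, m, seed=seed)
    return Graph([(str(u), str(v)) for u, v in G.edges()], vertices=[str(v) for v in G.nodes()])


# -- Poland road network ----------------------------------------------------
#
# The incidence below is a synthetic best-effort reconstruction of the road
# map from its published description: 18 vertices (12 cities/junctions with
# Table-1 style labels, 6 border crossings), 24 edges with the published
# lengths in ~100 km units, Szczecin (v18) reachable only through e20 and
# e21, and e21-e10-e9-e6-e5-e4 forming a path from v18 to the central city
# v7 (Lodz).  Individual edges were matched to Google-Maps driving distances
# where possible; the exact published figure is not machine-readable, so any
# result that depends on this incidence is transcription-dependent.

ROAD_INCIDENCE: tuple[tuple[str, str, str], ...] = (
    ("e1", "v7", "v8"),
    ("e2", "v1", "v2"),
    ("e3", "v2", "v3"),
    ("e4", "v3", "v7"),
    ("e5", "v5", "v3"),
    ("e6", "v6", "v5"),
    ("e7", "v6", "v4"),
    ("e8", "v8", "v17"),
    ("e9", "v8", "v6"),
    ("e10", "v1", "v8"),
    ("e11", "v2", "v12"),
    ("e12", "v6", "v15"),
    ("e13", "v9", "v17"),
    ("e14", "v15", "v16"),
    ("e15", "v3", "v11"),
    ("e16", "v3", "v4"),
    ("e17", "v4", "v13"),
    ("e18", "v4", "v14"),
    ("e19", "v8", "v15"),
    ("e20", "v18", "v9"),
    ("e21", "v18", "v1"),
    ("e22", "v2", "v4"),
    ("e23", "v4", "v15"),
    ("e24", "v1", "v10"),
)

ROAD_LENGTHS: dict[str, float] = {
    "e1": 1.44, "e2": 1.87, "e3": 1.69, "e4": 1.71, "e5": 0.69, "e6": 1.72,
    "e7": 2.25, "e8": 2.11, "e9": 0.93, "e10": 2.86, "e11": 1.84, "e12": 1.18,
    "e13": 2.95, "e14": 1.40, "e15": 0.96, "e16": 0.56, "e17": 0.75,
    "e18": 1.16, "e19": 1.75, "e20": 2.45, "e21": 2.89, "e22": 2.46,
    "e23": 2.82, "e24": 2.70,
}

ROAD_LABELS: dict[str, str] = {
    "v1": "Poznan", "v2": "Wroclaw", "v3": "Katowice", "v4": "Krakow",
    "v5": "highway interchange", "v6": "Radom", "v7": "Lodz", "v8": "Warszawa",
    "v9": "Gdansk", "v10": "Germany border cross", "v11": "Czechia border cross",
    "v12": "Czechia border cross", "v13": "Slovakia border cross",
    "v14": "Slovakia border cross", "v15": "Lublin", "v16": "Belarus border cross",
    "v17": "Bialystok", "v18": "Szczecin",
}

#: Vertices carrying population in the SIR scenario: the cities.  Border
#: crossings and the bare highway interchange hold no resident population.
ROAD_POPULATED: frozenset = frozenset(
    {"v1", "v2", "v3", "v4", "v6", "v7", "v8", "v9", "v15", "v17", "v18"}
)


def make_road_network(incidence=None, lengths=None) -> Graph:
    """Metric graph of the Poland road approximation (18 vertices, 24 edges).

    ``incidence`` is a sequence of ``(edge_id, u, v)`` rows and ``lengths`` a
    mapping ``edge_id -> length``; both default to the shipped transcription.
    Edge *k* (0-based) is the row named ``e{k+1}``.
    """
    if incidence is None:
        incidence = ROAD_INCIDENCE
    if lengths is None:
        lengths = ROAD_LENGTHS
    ids = [row[0] for row in incidence]
    missing = [eid for eid in ids if eid not in lengths]
    if missing:
        raise ValueError(f"no length for edges {missing}")
    extra = [eid for eid in lengths if eid not in ids]
    if extra:
        raise ValueError(f"lengths given for unknown edges {extra}")
    vertices = [f"v{i}" for i in range(1, 19)] if incidence is ROAD_INCIDENCE else None
    g = Graph(
        [(u, v) for _, u, v in incidence],
        vertices=vertices,
        lengths=[lengths[eid] for eid in ids],
        labels=ROAD_LABELS if incidence is ROAD_INCIDENCE else None,
    )
    return g


def make_contact_network(n: int = 39, extra_edges: int = 2, seed: int = 0) -> Graph:
    """Tree-like heterosexual contact network (default 39 vertices, 40 edges).

    Grown as a random bipartite attachment tree (each new individual names
    one prior contact of the opposite sex), then ``extra_edges`` additional
    bipartite edges close cycles.  Vertex labels alternate ``m``/``f``
    prefixes in the style of contact-tracing identifiers.
    """
    if n < 2:
        raise ValueError("need at least 2 vertices")
    rng = np.random.default_rng(seed)
    sexes = ["m" if i % 2 == 0 else "f" for i in range(n)]
    names = [f"{s}{i:03d}" for i, s in enumerate(sexes)]
    edges: list[tuple[str, str]] = []
    for i in range(1, n):
        opposite = [j for j in range(i) if sexes[j] != sexes[i]]
        j = int(rng.choice(opposite)) if opposite else i - 1
        edges.append((names[j], names[i]))
    existing = {frozenset(e) for e in edges}
    attempts = 0
    added = 0
    while added < extra_edges and attempts < 1000:
        attempts += 1
        i, j = rng.integers(0, n, size=2)
        if i == j or sexes[i] == sexes[j]:
            continue
        key = frozenset((names[i], names[j]))
        if key in existing:
            continue
        existing.add(key)
        edges.append((names[min(i, j)], names[max(i, j)]))
        added += 1
    return Graph(edges, vertices=names)
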