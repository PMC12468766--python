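# edgeperc

Edge percolation centrality and contagion simulation on networks.

When a contagion — a disease on a contact or transportation network, a virus
on a technological network — spreads *along edges*, the edges that matter
for intervention are those that are influential both topologically and in
their current infection state. Static measures such as edge betweenness see
only the topology. `edgeperc` implements **edge percolation centrality
(EPC)**, a time-dependent edge score that weighs shortest-path traffic by
the percolation states of the edges a contagion would start from, together
with the tooling needed to use it: file I/O and network generators, a
brute-force verification oracle, the complementary **edge hop distance
(EHD)**, two contagion simulators (a simple probabilistic edge contagion and
a diffusive SIR model on a metric graph), and a single-edge-removal
intervention scan.

## The measures

For an undirected network G = (V, E), let σ_ab be the number of shortest
paths from vertex a to vertex b and σ_ab(e) the number of those passing
through edge e. Normalized **edge betweenness** is

    EBC(e) = 1/(|V| (|V|−1)) · Σ_{a≠b} σ_ab(e) / σ_ab        (ordered pairs)

with a *raw* variant that counts unordered vertex pairs (on a tree: the
product of the component sizes created by deleting e). Given per-edge
percolation states x_e ∈ [0, 1] at time t (0 = susceptible, 1 = fully
percolated, in between = e.g. an infection density), **edge percolation
centrality** weighs each shortest path P by the state of its *source edge*
(the first edge leaving a) and normalizes by the percolation mass outside
the focal edge:

    EPC_t(e) = (|E|−1)/(|V| (|V|−1)) ·
               Σ_{a≠b} [ Σ_{P: a→b, e∈P} x_src(P) / σ_ab ] / ( Σ_i x_i − x_e )

When every edge carries the same state K > 0, EPC reduces edgewise to EBC —
the package verifies this identity to 1e-9 routinely, and checks the full
computation against an exhaustive path-enumeration oracle on small graphs.
**Edge hop distance** is the minimum hop count from an edge's endpoints to
any vertex touching an infected edge (0 if the edge itself is infected, ∞ if
nothing is).

The simulators put the measures to work: a discrete-time edge contagion
(susceptible edges adjacent to a percolated edge flip with probability p
each step) and a deterministic diffusive SIR model in which vertex SIR
compartments couple to infected line-densities diffusing along metric edges
(see `docs/methods.md`). The intervention scan removes each edge in turn,
re-simulates, and reports the change in the total area under the vertex
infection curves (ΔAUC; negative = removal mitigates the epidemic).

## Worked example

Generate the bundled example networks, then score the 8-vertex synthetic
tree (a star at v4 linked by the path e4–e5 to a fork at v6):

```sh
$ edgeperc make-fixtures --out-dir data
$ edgeperc ebc --graph data/synthetic_tree.tsv --mode raw
edge_id,u,v,value
e1,v1,v4,7.0
e2,v2,v4,7.0
e3,v3,v4,7.0
e4,v4,v5,16.0
e5,v5,v6,15.0
e6,v6,v7,7.0
e7,v6,v8,7.0
```

The two central edges dominate: deleting e4 separates 4×4 = 16 vertex
pairs, deleting e5 separates 5×3 = 15. Now give the right-hand fork edges
e6, e7 a high percolation state (0.5) and everything else 0.1:

```sh
$ printf 'e1,0.1\ne2,0.1\ne3,0.1\ne4,0.1\ne5,0.1\ne6,0.5\ne7,0.5\n' > states.csv
$ edgeperc epc --graph data/synthetic_tree.tsv --states states.csv
edge_id,u,v,value
e1,v1,v4,0.16836734693877553
e2,v2,v4,0.16836734693877553
e3,v3,v4,0.16836734693877553
e4,v4,v5,0.489795918367347
e5,v5,v6,0.5357142857142857
e6,v6,v7,0.5357142857142857
e7,v6,v8,0.5357142857142857
```

Although e4 separates more vertex pairs, e5 now outranks it (0.536 > 0.490)
because it sits next to the highly percolated fork; moving the high states
to the left star edges (e1, e3) flips the order back. That is the point of
the measure: identical topology, different percolation pattern, different
ranking.

Other subcommands: `ehd` (hop distance to the infected region),
`simulate-simple` (the probabilistic edge contagion, writing per-step
states, infected counts and the ΣEPC/ΣEBC ratio curve), `simulate-sir` and
`intervene` (the metric-graph SIR model and the ΔAUC edge-removal scan on,
e.g., the bundled 18-vertex road network, configured by
`data/sir_config.json`), and `benchmark` (EPC runtime scaling on scale-free
networks). Run `edgeperc COMMAND --help` for flags.

## Layout

| path | contents |
| --- | --- |
| `src/edgeperc/graph.py` | graph container, edge-list/GraphML I/O |
| `src/edgeperc/generators.py` | synthetic tree, scale-free, road and contact networks |
| `src/edgeperc/centrality.py` | EBC, EPC (+ oracle), EHD, ratio, benchmark |
| `src/edgeperc/contagion.py` | discrete-time probabilistic edge contagion |
| `src/edgeperc/sir.py` | diffusive SIR on a metric graph |
| `src/edgeperc/intervention.py` | ΔAUC single-edge-removal scan |
| `src/edgeperc/cli.py` | `edgeperc` command-line interface |
| `docs/methods.md` | models, numerics, design choices, limitations |
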