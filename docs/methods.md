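# Methods

This note documents the models implemented in `edgeperc`, the numerical
choices behind them, and what the bundled synthetic networks do and do not
represent.

## Edge percolation centrality

### Definition and conventions

Shortest paths are unweighted (hop-count) throughout; metric edge lengths
affect only the diffusive SIR dynamics. For ordered vertex pairs (a, b),
a ≠ b, with σ_ab shortest paths of which σ_ab(e) traverse edge e,

    EPC_t(e) = (|E|−1)/(|V|(|V|−1)) ·
               Σ_{(a,b)} [ Σ_{P: a→b, e∈P} x_src(P) / σ_ab ] / ( Σ_i x_i − x_e )

where x ∈ [0,1]^|E| are the percolation states at time t and src(P) is the
first edge of P leaving the source vertex a. Conventions that the bare
formula leaves open:

* **Multiple shortest paths with different first edges.** A pair's
  contribution is the average over its shortest paths through e of each
  path's own source-edge state, i.e. Σ_{P∋e} x_src(P) / σ_ab. This
  degenerates to the single-source-edge expression whenever all of a pair's
  paths share a first edge, and it preserves the uniform-percolation
  reduction to EBC exactly (the weights cancel against the denominator).
* **Degenerate denominator.** If Σ_i x_i − x_e ≤ 0 there is no percolation
  mass outside e and EPC(e) is defined as 0: the measure quantifies
  influence relative to percolation elsewhere. (The vertex-percolation
  analogue has the same gap.) A visible consequence: at the first step of a
  contagion with a single fully percolated edge, that edge's own EPC is 0
  while its neighbours on likely transmission paths score highest.
* **Disconnected pairs** (σ_ab = 0) contribute nothing, so EPC and EBC stay
  defined on disconnected graphs — required by the intervention scan, which
  deletes edges.
* Normalized EBC sums over ordered pairs with prefactor 1/(|V|(|V|−1));
  *raw* EBC reports the unordered-pair sum (σ_ab(e)/σ_ab summed once per
  pair), which on a tree is the integer n_left·n_right.

### Algorithm and oracle

`epc` runs one Brandes-style dependency sweep per source vertex
(O(|V||E|) for the whole vector): alongside the path counts σ it propagates
σ_x(v), the sum over shortest source→v paths of their first-edge states,
with the same predecessor recursion seeded by the states of the source's
own edges. The per-DAG-edge accumulation then weighs the classic Brandes
edge term by x_e (for edges leaving the source) or σ_x(u)/σ(u) (further
down), which is exactly the per-pair average above. Path counting is exact
(integer-valued floats; no floating-point distances), so the only rounding
is in the final weighting.

`epc_oracle` enumerates every shortest path of every ordered pair by a
layered DAG walk and applies the formula literally. It is exponential in
the worst case and guarded to |V| ≤ 12; the test suite checks
max|epc − epc_oracle| < 1e-9 over hundreds of random graphs and states, and
`benchmark_epc` reports (never asserts — it is hardware-dependent) the
empirical log-log scaling slope of the fast path on scale-free networks.

### Edge hop distance

EHD(e) = 0 if x_e > 0; ∞ if x ≡ 0; otherwise the minimum unweighted
distance from either endpoint of e to any vertex incident to a
nonzero-state edge, computed by one multi-source BFS. Hop counts are used
even on metric graphs — EHD is a step-count measure by construction.

## Simple edge contagion

Binary edge states, synchronous discrete time: every susceptible edge with
at least one percolated neighbour (shared endpoint) flips with probability
p per step, independently, with no recovery. One seeded generator per run,
draws consumed in stable edge-index order, so trajectories are
bit-reproducible. Two deliberate choices:

* **Synchronous updates** computed from the step-start state — the
  reproducible reading of "conditional on being adjacent to at least one
  percolated edge"; asynchronous orderings are unspecified.
* **Flat hazard**: an edge with k > 1 percolated neighbours still flips
  with probability p, not 1−(1−p)^k; the per-neighbour hazard is available
  as `per_neighbor=True`.

With p = 1 the spread equals breadth-first layers on the line graph, which
the tests use as an exact oracle. Once every edge is percolated the ratio
ΣEPC/ΣEBC equals 1 at every later step (the uniform-percolation
reduction); with 0 < p < 1 on a connected graph full percolation is
reached with probability 1.

The default study conditions for this simulator are p = 0.2 over 40 steps
from a single peripheral edge, on a 39-vertex / 40-edge tree-like contact
network. The bundled generator grows a random bipartite attachment tree
plus two cycle-closing edges with contact-tracing-style m/f labels: it
reproduces the size, sparsity and bipartite structure of a real outbreak
component, not its actual topology.

## Diffusive SIR on a metric graph

### Model

Vertices carry SIR compartments; edges carry an infected line density
I_e(x, t):

    S_v' = −τ_v S_v I_v
    I_v' =  τ_v S_v I_v − η_v I_v + Σ_{e∼v} α_ev I_e(v, t) − (Σ_{e∼v} λ_ev) I_v
    R_v' =  η_v I_v
    ∂_t I_e = d_e ∂_x² I_e

coupled by a flux-balance (Kirchhoff–Robin) condition at each vertex: the
outward diffusive flux of edge e at v equals injection λ_ev I_v minus
absorption α_ev I_e(v) plus net edge-to-edge transfer
Σ_{e'≠e} ν (I_{e'}(v) − I_e(v)). This assembly is chosen so that the total
population Σ_v (S+I+R) + Σ_e ∫ I_e dx is conserved *exactly* (to machine
precision per explicit step); it is one concrete realization of a
vertex-coupling matrix family whose general construction lives in the
specialist literature on reaction–diffusion over metric graphs, and other
realizations need not conserve mass the same way.

Parameters (defaults = the road-network scenario): τ = 0.45, η = 0.13
(note τ·S₀ = 0.1125 < η: each vertex is locally subcritical and the
epidemic is transport-driven), d = 1.5, α = 0.125, ν = 0.1, Δt = 0.02,
Δx = 0.55, with per-vertex populations S₀ = 0.25 at populated vertices and
a seed vertex starting at (S, I) = (S₀−10⁻⁶, 10⁻⁶). Unpopulated vertices
(border crossings, bare junctions) carry no compartments: by default they
neither inject nor absorb ("reflecting"), so their S = I = R stay
identically zero and density passes through them only via the ν terms;
`border_mode="absorbing"` instead discards density reaching them
(an open-boundary reading of "border crossings stay at zero"). The
departure rate reading `lambda_mode` defaults to λ_ev = 0.1/deg(v) — a
fixed total departure budget per vertex, the bounded interpretation —
with `"per_edge"` (0.1 each) and `"times_degree"` (0.1·deg) selectable,
since the printed form "0.1deg(v)" is typographically ambiguous.

### Discretization

Each edge gets a uniform grid of n_e = max(3, round(l_e/Δx)+1) points
(spacing Δx_e = l_e/(n_e−1); the clamp keeps an interior point on edges
shorter than 2Δx, at the cost of a locally finer spacing). Interior points
use the standard second-difference stencil; endpoint samples are updated as
half-cells of width Δx_e/2 receiving the discrete flux plus the boundary
source terms, which is what makes the conservation exact under forward
Euler. Construction refuses configurations violating the per-edge CFL
bound d·Δt/Δx_e² ≤ 1/2 (the road scenario sits at ≈ 0.1–0.38) and the
stepper raises on NaNs or departures below −10⁻³. Forward Euler is used
for both ODEs and PDE — the simplest scheme consistent with the printed
step sizes; halving Δt changes the road-network vertex curves by well
under 1% sup-norm, and positivity violations stay below 10⁻⁹ at the
default steps. The per-edge percolation state handed to EPC/EHD is the
arithmetic mean of the edge's grid samples, clipped to [0, 1] (maximum and
endpoint values are plausible alternatives; the mean is the default
because it is what an "infection density along a road" most directly
suggests).

The default horizon is t_end = 20 (1000 solver steps, sampled every 10 —
i.e. 100 recorded steps of the sampled series).

### The road network

The bundled 18-vertex / 24-edge metric graph approximates Poland's major
roads: 11 populated cities, 6 border crossings, one bare highway
interchange, edge lengths in ~100 km units. The published source for this
map is a figure, not a table, so the shipped incidence
(`generators.ROAD_INCIDENCE`) is a synthetic best-effort transcription:
it honours every adjacency stated in the accompanying text (Szczecin
reachable only through e20/e21; e21–e10–e9–e6–e5–e4 forming a corridor
from Szczecin to the central city; remote south/east edges e14/e18) and
matches individual lengths to driving distances where possible. **Any
numerical result that depends on this incidence — per-edge EPC rankings,
ΔAUC signs — is transcription-dependent** and is treated as such in the
tests.

## Intervention scan

For each edge e, the scan rebuilds the problem on G − e with identical
parameters and initial condition (unremoved edges keep their grids, so
differences are attributable to topology; degree-dependent departure rates
are recomputed on the pruned graph — a closed road's travellers
redistribute), simulates to t_end, and reports

    ΔAUC(e) = Σ_v ∫ I_v dt |_{G−e}  −  Σ_v ∫ I_v dt |_G

by the trapezoidal rule on the sampled curves, optionally multiplied by a
population scale (`auc_scale`, default 1 — the "population-level" scale is
not pinned down by the source material, so only signs and rankings are
meaningful). Negative ΔAUC = beneficial removal. Vertices isolated by a
removal keep running their local dynamics (their infection decays by η)
and still count toward the sum. The scan is deterministic; a removal whose
simulation diverges is recorded and excluded rather than aborting.

A caution from our own experiments: with the default (locally subcritical)
parameters, ΔAUC on the road scenario is dominated by *transit-time*
effects — how quickly infected mass reaches populated vertices and how
long it sits there versus on roads — rather than by which regions an edge
gates. In particular, removing the shorter of the two seed-vertex
corridors is consistently the most beneficial intervention across every
parameter reading we tried, and conclusions drawn from ΔAUC under a
conservative solver should be read with that mechanism in mind.

## Scope and limitations

* Graphs are simple and undirected; no multi-edges, directed edges, or
  vertex weights. Weighted-shortest-path EPC is out of scope.
* The synthetic generators reproduce sizes, sparsity and qualitative
  structure of the motivating real networks, not their actual wiring; the
  road incidence is a transcription (above).
* The SIR solver is explicit and first-order; it is meant for the small
  metric graphs it ships with, not for large networks or stiff parameter
  regimes.
* EPC is O(|V||E|) per evaluation but the oracle is exponential; keep
  `epc_oracle` to toy graphs.
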