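# Methods

## Problem setting

A true simple undirected network `G = (V, E)` is observed through an
imperfect channel, giving `G′ = (V′, E′)`. An attack strategy ranks the nodes
of `G′`; the top `round(p·|V|)` nodes are then removed from (or immunized in)
the **true** network `G`, and the damage is measured there. Two observation
channels are modelled, applied separately (their combination is out of
scope): link errors and node sampling.

## Generators

**Barabási–Albert.** Growth starts from a single node; node `k`
(k = 1, …, n−1) attaches `min(m, k)` edges to distinct earlier nodes. A
target is drawn with probability proportional to `degree + 1` (shifted-linear
kernel, the igraph generator default, implemented as a sampling bag holding
each node `degree + 1` times with within-round duplicates rejected). The edge
count is therefore exactly `Σ_k min(m, k) = 1 + 2(n−2)` for m = 2 — 19,997
links at n = 10,000. The kernel choice is observable: pure degree-proportional
attachment yields average local clustering ≈ 0.0044 at n = 10,000, m = 2,
while the shifted kernel yields ≈ 0.0021 and average shortest path ≈ 5.39,
the regime this package targets. Defaults: n = 10,000, m = 2.

**Geometric random graph.** `n` points i.i.d. uniform on the unit square;
edge iff Euclidean distance ≤ r (KD-tree range query, so a draw at n = 10,000
takes well under a second). Defaults: n = 10,000, r = 0.015, giving mean
degree ≈ 7 and mean link count with closed-form expectation
`C(n,2)·(πr² − (8/3)r³ + r⁴/2)` ≈ 34,893, used as an analytic oracle in the
tests. At these defaults a draw contains a giant component holding ≈ 99.3% of
nodes but almost surely a handful of isolated nodes (≈ n·e^{−πr²n} ≈ 8), so
full connectivity is essentially unattainable; `require_connected` is
therefore **off** by default (it regenerates up to a retry cap when enabled,
which is practical only for denser small graphs). Path-length statistics use
the reachable-pairs convention (below), which is well defined on such draws.

## Observation models

**Link errors.** Exactly `round(|E|·δ)` edges are deleted uniformly, then
exactly `round(|E|·α)` edges are added, drawn uniformly without replacement
from the pairs non-adjacent *after* deletion (self-loops excluded). The two
steps are sequential, so a deleted edge may be re-added; `|E′| = |E| −
round(|E|δ) + round(|E|α)` holds for every seed. Additions use rejection
sampling with a dense-graph fallback that enumerates absent pairs.

**Node sampling.** The quota is `round(p_s·|V|)` nodes; the observed network
is the induced subgraph. BFS and DFS traverse from a uniform start with
randomized neighbor order (BFS marks on enqueue, DFS on pop); SEC greedily
adds the unsampled neighbor with the most edges into the current sample, ties
uniform. All three restart from a uniform unvisited node if the frontier
empties before the quota — necessary on disconnected inputs — and the number
of restarts is reported, since a restart-free crawl of a connected graph
induces a connected observed network. RAND draws uniformly without
replacement.

All fraction-to-count conversions package-wide use round-half-up.

## Attack strategies

`Degree` is static (computed once on `G′`); `HDA` removes a
current-maximum-degree node and recomputes; `CI(ℓ)` scores
`(k_i − 1)·Σ_{j∈∂Ball(i,ℓ)}(k_j − 1)` over the ring at hop distance exactly
ℓ (so degree ≤ 1 nodes score 0) and is used adaptively. After removing `x`,
only nodes within hop distance ℓ+1 of `x` can change score: a changed ball
membership requires `dist(j,x) ≤ ℓ`, and a changed boundary degree requires a
neighbor of `x` on the ring, i.e. `dist(j,x) ≤ ℓ+1`. Rescoring that
neighborhood is exactly equivalent to full recomputation; the test suite
checks the adaptive orders step-by-step against brute-force recomputation
oracles on hundreds of small random graphs. Adaptive orders use a lazy
max-heap with per-push random keys, which breaks ties uniformly. Ball radii
ℓ = 1 and ℓ = 2 are the supported study settings (any ℓ ≥ 1 works).

Ranking comparisons between the true and observed views use **static** score
vectors (degree; CI values on the intact graphs): Spearman correlation of
node rankings is naturally score-based, and adaptive removal positions are
confounded by tie randomization. Both routes exist in the API; static is the
default. Unobserved nodes (outside a sample) receive the lowest rank, tied
and averaged; the correlation itself is the Pearson correlation of
tied-average rank vectors. One side constant returns 0 by convention; both
sides constant raises.

## Evaluation

**GC curves.** For each removal fraction `p` on a grid (default 0.00–0.50 in
steps of 0.02, matching the region where fragmentation happens), the top
`min(round(p·|V|), |order|)` nodes are removed from `G` and the largest
connected component is measured **relative to the original |V|** (not the
initial GC size; the two are nearly identical on these near-connected
networks). The cap implements the sampling-scenario rule that one cannot
remove more nodes than were sampled, producing plateaus past `p = p_s`.
Curves are computed with a reverse union-find (nodes added back from the
fully attacked graph), which equals per-point recomputation and is tested
against it. The trapezoidal area under a curve serves as a scalar
attack-quality summary.

**SIR immunization.** Discrete-time synchronous dynamics: at each step every
susceptible node is infected independently with probability β per currently
infected neighbor (i.e. `1 − (1−β)^{#infected neighbors}`), then every node
infected at the start of the step recovers with probability γ — a node can
transmit in the step it recovers. β and γ are per-step probabilities
(defaults 0.1 and 0.01); a continuous-time formulation would be an equally
defensible reading of the rates, but the discrete chain is the common
convention in this simulation literature and is fixed here for
reproducibility. Immunized nodes are removed from the transmission graph
entirely (cannot infect or be infected) yet count in both the numerator and
denominator of the outcome, `(final S + M)/|V|`. The epidemic starts from one
uniform non-immunized node and terminates when no infected remain (guaranteed
for γ > 0; a step cap raises a diagnostic otherwise). The adjacency matrix of
the non-immunized subgraph is built once per immunization set and reused
across replicate runs.

## Experiment orchestration and seeding

`run_experiment` walks a factorial grid (one incompleteness mode per config)
with `n_observed_replicates` observed networks per cell, evaluating GC curves
and optionally SIR curves, and emits a long-format table; `summarize` adds
mean/sd over replicates. Every stochastic call gets a child
`numpy.random.Generator` from `SeedSequence([master_seed,
crc32(stable_path_key)])`, so tables are bit-identical for identical
(config, master_seed) and independent of evaluation order. Full-scale
replication of the published protocol (100 observed networks × 1,000 SIR
runs per cell at n = 10,000) is a long-running batch job driven through the
same config machinery; tests and examples run reduced grids.

## Statistics conventions

Average local clustering is the Watts–Strogatz mean of per-node local
coefficients with degree < 2 nodes contributing 0. Average shortest path is
the mean hop distance over unordered *reachable* pairs — the only convention
finite on disconnected graphs and the one igraph reports. Both are computed
through igraph's C core for 10,000-node tractability and are verified against
exhaustive per-pair BFS / triangle-count oracles on small graphs.

## What the synthetic generators do and do not capture

The BA family reproduces the heavy-tailed degree distributions under which
attack strategies are known to be potent and link errors relatively benign;
the GRG family gives the opposite regime (narrow degree distribution, strong
locality, huge diameter). Real inferred networks additionally have degree
correlations, community structure and *structured* (non-uniform) measurement
error, none of which the uniform δ/α model or the i.i.d. spatial model
emulates — conclusions from passing tests transfer to real data only insofar
as degree-distribution shape is the dominant factor. The reduced scales used
in the ordering tests (n = 2,000, 10 replicates) were chosen as the smallest
sizes at which the qualitative orderings are stable across seeds.

## Known limitations

Directed/weighted graphs, combined error+sampling channels, SIS/SEIR
dynamics, and non-uniform initial infections are out of scope. The SEC
sampler's tie-breaking and restart policy follow the greedy
max-edges-into-sample reading with uniform ties; other published variants
differ in detail. Degree-preserving noise models are not implemented.
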