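# Methods

## Model and assumptions

All computations operate on simple undirected graphs. Readers symmetrize
directed edges, collapse duplicates and drop self-loops regardless of what
the source file declares, because none of the centralities here uses
direction or weights. Isolated nodes are kept; they receive zero for all
four attributes and a spread size of 1.

The LWC score treats node ranking as a multi-attribute decision problem:
nodes are alternatives, the four local attributes (degree `k`, two-hop
degree `thk`, clustering coefficient `clc`, two-hop clustering coefficient
`thclc`) are criteria, and criterion weights come from the entropy-weight
method. The underlying assumption is that an attribute whose normalized
distribution over nodes is close to uniform does not separate nodes and
should count less; the weight of attribute *j* is proportional to
`1 − E_j`, the entropy deficit of its normalized column.

### Two-hop degree

`thk_i` is operationalized as the size of the distance-≤2 ball around *i*
minus the node itself (a depth-2 BFS count). This is the "distinct union"
reading: neighbors shared by several one-hop neighbors are counted once,
and one-hop neighbors themselves are inside the ball. It makes
`thk_i ≥ k_i` with equality exactly when no node sits at distance 2, and
`thk_i ≤ n − 1`. The alternative multiset reading (sum of neighbor degrees
minus overlap corrections) collapses to the same count once duplicates and
the root are removed, which is why the distinct-union form is implemented
directly.

### Degenerate inputs of the weighting step

* `clc_i := 0` for `k_i ≤ 1` (the defining ratio divides by `k(k−1)`);
  this keeps trees and leaves finite.
* An all-zero attribute column (e.g. `clc` on any triangle-free graph)
  would get entropy 0 and hence the *largest* weight from the raw formula,
  despite carrying no information. Its weight is forced to 0 before
  renormalizing — consistent with the intent of entropy weighting, which
  rewards discriminating attributes.
* If every informative column is constant (vertex-transitive graphs), the
  weight formula is 0/0; weights fall back to uniform over the informative
  columns. Any choice yields the same total-tie ranking, so the fallback
  only fixes numerics.
* Normalization cancels uniform scaling of any raw column, so scores are
  invariant under attribute rescaling (property-tested).

### Ranking and ties

Scores are rounded to 10 decimal places before grouping into ranks; tied
nodes share a dense rank (1, 2, … over distinct values) and are listed in
label order, so ranking lists are fully deterministic. The rounding
threshold exists because the tie-sensitive metrics (monotonicity, tau-a)
need a reproducible equality test on floats; 1e−10 is far below any
meaningful score separation (scores sum to 1 over nodes) and far above
accumulated floating-point error.

## Baselines

Betweenness is the unnormalized Brandes accumulation over unordered pairs
with endpoints excluded (validated in the tests against exhaustive
geodesic enumeration on ≤8-node graphs). Closeness uses the reciprocal of
the distance sum on connected graphs and switches to the harmonic sum
`Σ 1/d` (with `1/∞ = 0`) when unreachable pairs exist — the two standard
conventions; the study networks are connected so the branch never matters
for table reproduction. Local centrality aggregates two-hop neighborhood
sizes over two levels of neighbors; clustered local degree is
`(1 + clc_i) · Σ_{j∈N(i)} k_j` with the *neighbors'* degrees in the sum (a
sum over `j` of a constant `k_i` would make the index dead; the original
CLD construction uses neighbor degrees).

## SIR ground truth

Discrete-time, synchronous: each step every infected node tries to infect
each susceptible neighbor independently with probability β, then recovers
with probability γ (default 1). Spread size counts all ever-infected nodes
including the seed, so β=0 gives exactly 1 and β=γ=1 on a connected graph
gives exactly *n* (a BFS wave). Influence is the mean spread over `runs`
(default 100) simulations per seed node.

Because a susceptible node with *m* infected neighbors is infected with
probability `1 − (1−β)^m`, all runs for one seed node are simulated as one
vectorized batch (boolean state matrices, a sparse adjacency product per
step) — distributionally identical to per-edge Bernoulli draws and about
two orders of magnitude faster than a per-edge loop. RNG substreams are
spawned per seed node from the master seed and the node's position in
sorted label order, so the influence table is bit-identical across runs
and independent of node iteration order. This is a deliberate coarsening
of per-(node, run) substreams: batching runs inside one stream preserves
both reproducibility properties while enabling the vectorized form.

β is rarely stated in spreading studies; the default is
`β = 1.5 × ⟨k⟩/(⟨k²⟩−⟨k⟩)` (1.5× the degree-based epidemic threshold,
capped at 1). Slightly supercritical spreading is the usual operating
point for spreader-ranking evaluation: subcritical outbreaks die
immediately and make all nodes look alike, strongly supercritical ones
saturate the graph. The resolved value is echoed into every report.

## Evaluation metrics

* Monotonicity `M(S) = [1 − Σ_s |V|_s(|V|_s−1) / (|V|(|V|−1))]²` depends
  only on the tie pattern; 1 means all ranks distinct.
* The CCDF of scores is reported over distinct score thresholds
  (descending); the step count equals the number of distinct ranks, which
  is what the discrimination argument needs, so the axis convention is
  immaterial.
* Kendall τ is the tau-a form, the literal pairwise sign sum divided by
  `N(N−1)/2`, with no tie correction — tie-heavy rankings (degree) are
  penalized, which is the intended behavior of the protocol. Computed
  blockwise in O(n²) (exact), fine for the network sizes used here.
* Imprecision `ε(p) = 1 − M(p)/M_eff(p)` uses the top `⌈pN⌉` nodes of each
  list (ceiling keeps small-p sets non-empty); boundary ties are resolved
  by the rankings' deterministic order. Values are reported unclamped — a
  slightly negative ε under Monte-Carlo noise is diagnostic, not an error.
* Jaccard top-T is the intersection-over-union of top-T node sets.

## Synthetic data

The generators provide the two degree regimes the evaluation needs:
Erdős–Rényi G(n, p) (homogeneous) and Barabási–Albert (heavy-tailed),
both fully seeded. The BA generator starts from a complete graph on m+1
nodes and attaches each new node to m distinct degree-proportional
targets, giving exactly `m(n−m−1) + C(m+1,2)` edges. A Watts–Strogatz
generator is deliberately omitted — nothing in the test surface needs a
small-world regime that ER/BA do not already cover. The toy registry
(triangles, cliques, cycles, paths, stars, triangle-with-tail) uses small
integer labels so every attribute value can be checked by hand.

Synthetic graphs emulate the degree structure of real networks but not
their community structure, degree correlations or clustering profiles;
passing tests on them demonstrate correctness of the computations and
qualitative behavior of the metrics, not that LWC outperforms baselines
on any particular real network. The published comparison tables are
reproduced only when the four public study networks (football,
netscience — reduced to its 379-node largest component, email, power) are
present under `data/real/`; `lwcent.datasets.fetch` downloads them from
their public archives.

## Problem sizes and budgets

The acceptance script evaluates 200-node BA and ER networks with 100 SIR
runs per seed node and all six methods — large enough for the metrics to
be stable and heavy-tailed/homogeneous regimes to differ, small enough to
run in seconds. The β-monotonicity check uses BA(200, 2) with 500 runs per
node at four β values. Monte-Carlo assertions in the tests (star center
vs. leaf, β-monotonicity, BA-vs-ER degree tails) use fixed seeds and
margins wide enough that they are not knife-edge.

## Known limitations

* Static, undirected, unweighted graphs only.
* tau-a (not tau-b) is intentional; comparisons with tie-corrected
  implementations elsewhere will differ on tie-heavy methods.
* The SIR simulator is synchronous and generation-based; continuous-time
  (Gillespie) dynamics would give different absolute spread sizes, though
  rank-based conclusions are typically insensitive.
* The entropy weighting can concentrate weight on the clustering columns
  in graphs where clustering is sparse but highly discriminating (visible
  on ER graphs, where LWC's τ against the SIR truth trails degree-based
  baselines); the method's published advantages were demonstrated on real
  social/infrastructure networks, and the acceptance script reports
  whatever the synthetic networks actually yield.
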