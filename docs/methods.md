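# Methods

This note records the models, conventions and numerical choices behind
the package, including every place where the underlying method left a
genuine design decision open.

## Graph model and coercion

All computations run on simple undirected unweighted graphs
`G(V, E)` with adjacency `a_ij ∈ {0,1}`.  Any input (edge list, GML,
GraphML; directed, weighted, or multigraph) is coerced at load:
directed edges are symmetrized, weights and attributes dropped,
self-loops and duplicate edges removed, with a logged count of dropped
records.  Node labels are opaque and kept in first-seen order.
Disconnected graphs are accepted; path-based indicators (betweenness,
closeness, information centrality) are computed within connected
components, and pairs in different components contribute nothing.

The coercion matters for reproducibility: the classic karate-club
dataset, for example, ships with edge weights, and feeding the weighted
adjacency to the eigenvector step changes role assignments (see
"Known limitations").

## Ego networks

The one-layer ego network of `v` is the induced subgraph on `v` and its
neighbors.  The **two-layer** ego network is defined as the *union of
the one-layer ego networks of `v` and its neighbors*.  Its node set
equals the radius-2 ball around `v`, but it is not the induced subgraph
on that ball: an edge between two distance-2 nodes is kept only when
both endpoints fall inside a common neighbor's ego network.  This union
form is the definition under which the published karate-club role
counts reproduce; the induced radius-2 subgraph gives a different
ego-variant answer on that graph.  Every two-layer edge is still an
edge of `G` between retained nodes.

## Indicators

The 13-indicator vocabulary: degree, relative closeness, absolute
betweenness, ego-betweenness, eigenvector, ego-eigenvector, information
centrality, ego-information, clustering, and Burt's effective size,
efficiency, constraint and hierarchy.

Conventions for degenerate nodes: clustering is 0 for degree < 2;
structural-hole measures are all 0 for isolated nodes (warned);
closeness of an isolated node is 0; the eigenvector of an edgeless
graph is identically 0 (warned).

**Eigenvector centrality** is the principal adjacency eigenvector,
normalized so the maximum component is 1.  It is computed by power
iteration on `A + I` — the shift leaves the eigenvectors unchanged and
makes the matrix primitive on connected graphs, so bipartite `±λ`
eigenvalue pairs cannot stall convergence.  Deterministic all-ones
start; convergence when successive max-normalized iterates differ by
less than 1e-10 in max-norm; 10,000-iteration cap.  On disconnected
graphs the iteration runs on the whole matrix and the positive start
vector settles mass on the component(s) attaining the spectral radius;
other components go to 0.  The ego variant computes, for each node, its
own component of the principal eigenvector of its two-layer ego
network, max-normalized within that subgraph; values are therefore
comparable across nodes as "relative prominence inside one's own
horizon".

**Information centrality** uses the information matrix
`B = D − A + J` per connected component (`D` the degree diagonal), with
`C = B⁻¹`, `T = trace(C)`, `R` the row sum of `C` (constant by
construction for both `J` choices), and node value
`I_v = 1/(C_vv + (T − 2R)/n)`.  Two regularizations are offered:

* `identity` (default): `J = I`.  This is the form the method's source
  material states, and it is the form under which the published
  degree–information correlation levels on model networks reproduce
  (e.g. Pearson ≈ 0.96 on Watts-Strogatz graphs, vs ≈ 0.57 under the
  all-ones form, which is far from the published 0.99).
* `ones`: the classical Stephenson–Zelen `J = 1·1ᵀ`.

The linear system is solved with a symmetric positive-definite
factorization; `B` is always invertible on a connected component.

**Structural holes** follow Burt with proportional tie strengths
`p_ij = a_ij/k_i`: effective size `ES_v = Σ_j [1 − Σ_q p_vq m_jq]`
(`m_jq = a_jq / max_q' a_jq'`), efficiency `ES_v/k_v`, constraint
`C_v = Σ_j (p_vj + Σ_q p_vq p_qj)²`, and hierarchy as the Coleman–Theil
concentration of the per-neighbor constraint terms,
`Σ_j (c_vj/(C_v/k)) ln(c_vj/(C_v/k)) / (k ln k)` (0 for `k ≤ 1`).
Effective size and constraint are delegated to networkx; efficiency and
hierarchy are computed here.  All are cross-checked against an
independent brute-force evaluation of the defining sums.

**Betweenness** is absolute (unnormalized), each unordered pair counted
once, endpoints excluded; ego-betweenness is the same quantity for the
ego inside its one-layer ego network.

## EIMI

`I_i = α·I_D + β·I_EB + γ·I_E` with each component divided by its
maximum over nodes.  Max-normalization (rather than min–max) keeps
zeros at zero and the top node at exactly 1; min–max is available as an
option.  Default weights are equal (α=β=γ=1, totals in [0,3]); the
ranking is invariant to the common scale, and automatic weight
optimization is deliberately out of scope.  The `global` variant uses
whole-graph eigenvector centrality; the `ego` variant uses
ego-eigenvector.  Ego-betweenness (not global betweenness) is used in
*both* variants: the indicator triple is fixed, and only the
eigenvector component switches.

## RUMI

Ranks are descending; tied indicator values share a rank.  Values are
rounded to 9 decimals before grouping so that exact structural
symmetries (automorphic nodes) tie despite floating-point noise —
without this, eigenvector components that are equal by symmetry split
into separate ranks and the double-star worked example fails.

Two tie-handling schemes are supported, and the choice is consequential
on graphs with heavy degree ties:

* `dense` (default): ranks 1,2,2,3.  With `Rn ≥` the number of distinct
  degree values, *every* node is a core candidate, which is what lets
  near-regular networks (ER, WS, and e.g. a round-robin football
  schedule) return far more cores than `Rn` and essentially never a
  bridge — the behavior reported for homogeneous model networks.
* `competition`: ranks 1,2,2,4.  Candidate pools behave like "top-Rn
  positions", which reproduces the published karate-club analysis
  (4 cores {0,1,2,33} with `Rn = 7`); under dense ranking that graph
  returns 9 cores.

No single scheme reproduces both published behaviors; the package
defaults to `dense` and exposes `ranking="competition"`.

Thresholds are inclusive (`≥`).  The rank-difference averages are
plain arithmetic means over all `N` nodes and may be negative.
`Rn` defaults to round-half-up of `N/⟨k⟩`, floored at 1, and refuses to
guess when `⟨k⟩ < 3` (supply the degree-distribution inflection point
explicitly; no automatic knee detector is trusted).  Under competition
ranking the double-star worked example needs `Rn = 2` (the bridge's
ego-betweenness rank sits at 3, behind the two tied hubs); under the
dense default it reproduces at `Rn = 1`.

## Synthetic generators

The generators encode the evaluation conditions: ER `G(n, p)` with
`p = ⟨k⟩/(n−1)`, Barabasi-Albert with `m = ⟨k⟩/2`, Watts-Strogatz ring
lattice with even degree `⟨k⟩` and rewiring probability 0.1 (the
original studies' generator variants are not public; standard
constructions with matched `N` and `⟨k⟩` are used, and the rewiring
probability is exposed).  Ten replicates per family at `n = 200`,
`⟨k⟩ = 4`; replicate seeds spawn from one base seed via numpy's
SeedSequence, and identical spec + seed gives identical edge lists.

The double-star fixture (defaults `n_left = n_right = 6`, one asymmetry
edge, 13 nodes) places the asymmetry edge *between* a left leaf and a
right leaf.  This keeps the two hubs exchangeable under an automorphism
— equal degree and exactly tied on every whole-graph indicator — while
their two-layer ego networks differ.  Putting the extra edge among the
leaves of one hub instead would lower that hub's ego-betweenness
(15 → 14), break the tie, and push the bridge's ego-betweenness rank
out of the candidate pool at `Rn = 1`, so no ranking scheme could
recover the intended role assignment; the cross placement is the
construction under which the worked example is self-consistent.

What the generators do *not* emulate: community structure, degree
assortativity, clustering levels of real social networks, or the exact
degree distributions of the original tools' model variants.  Passing
results on them demonstrate the method's behavior on homogeneous vs
degree-heterogeneous topology, not performance on any particular real
network.

## Baselines

PageRank (damping 0.85, tolerance 1e-10, uniform teleport; each
undirected edge acts as two arcs) and HITS.  On an undirected graph the
HITS hub/authority fixed point is the principal adjacency eigenvector;
it is computed by dense symmetric eigendecomposition, which doubles as
an independent cross-check of the power-iteration eigenvector.
Rank agreement between score vectors reports the Spearman correlation
and the top-k overlap fraction, with tie groups truncated
deterministically by label order.

## Known limitations

* On the karate club, the ego-variant role counts reproduce the
  published values exactly (4 cores, 4 bridges, competition ranking,
  `Rn = 7`), and the global variant reproduces the 4-core set
  {0, 1, 2, 33}; the global *bridge* count comes out 3 rather than the
  published 5.  The published count is recovered only if the eigenvector
  step is fed the *weighted* karate adjacency, which the package's
  unweighted contract deliberately rejects.
* Correlation levels on Barabasi-Albert graphs
  (Spearman degree vs ego-betweenness / effective size) measure
  0.967–0.978 across seed blocks — at, and occasionally just under, the
  0.97 level the published tables round to 1.00.
* Core *counts* on homogeneous model networks depend strongly on the
  tie structure of the generator and are not a stable quantity; only
  the bridge counts (zero) are.
* The method is designed for degree-heterogeneous (scale-free-like)
  networks; on homogeneous networks it flags ~20% of nodes as cores,
  which the original analysis itself calls too many.
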