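# Methods

## Problem setting

Protein complexes and functional modules appear in protein–protein
interaction (PPI) networks as subgraphs, but curated interaction databases
are sparse: many proteins that act together have no recorded edge.  Gene
Ontology (GO) annotations carry an independent functional signal.  `ppimod`
turns that signal into *must-link prior knowledge* — pairs of gene products
with near-perfect semantic similarity — and injects it into module
detection in two ways: as additional network edges, and as pairwise
constraints that supervise the clustering itself.

## Semantic similarity

For each GO namespace (biological process, cellular component, molecular
function) treated independently, a term's cumulative frequency is

    freq(c) = Σ { occur(cᵢ) : c ∈ Ancestors(cᵢ) },    p(c) = freq(c) / freq(root),

with `occur` counting one occurrence per distinct (gene, term) annotation
and `Ancestors` the reflexive-transitive `is_a` closure.  Because a term's
descendants are a subset of its ancestors' descendants, `freq` is monotone
non-decreasing toward the root and `p(root) = 1`.  The relevance similarity
between terms c₁, c₂ is

    sim(c₁, c₂) = max over common ancestors c of
                  [ 2 ln p(c) / (ln p(c₁) + ln p(c₂)) ] · (1 − p(c)).

The first factor is Lin's shared-information ratio; the second discounts
uninformative ancestors, so two terms whose only common ancestor is the
root score 0 and `sim(c, c) = 1 − p(c)`.  Natural logarithms are used (the
information-content convention); the 0/0 case when both terms are the root
is fixed at 0 because the relevance factor vanishes there.

Gene-product similarity aggregates term similarities by MAX over all cross
term pairs within a namespace and then MAX across the namespaces both
genes are annotated in.  MAX (rather than an average or a composite) keeps
the extraction of near-perfect pairs sharp: two multifunctional proteins
that share even one highly specific function are functionally linked for
the purpose of complex membership.  A pair annotated in disjoint
namespaces is UNDEFINED — a first-class sentinel distinct from a
similarity of zero, because "not comparable" and "comparable but
unrelated" behave differently downstream (UNDEFINED pairs can never become
constraints).  Functional pairs are the defined pairs with similarity ≥ a
threshold; ≥ is used because tiered pair sets are defined by closed
thresholds (1.0, 0.999, 0.998, 0.997) and 0.999 is the default.

## Topological metrics

Networks are simple undirected graphs: self-loops and edge direction are
dropped on input, duplicate edges collapsed.  Four metrics drive the
detectors:

* **Node clustering coefficient** `2 n_v / (k_v (k_v − 1))` with `n_v` the
  triangles through v; 0 when `k_v ≤ 1`.
* **Edge clustering coefficient** `S_cc(i,j) = z_ij / min(k_i − 1, k_j − 1)`
  with `z_ij` the triangles on the edge; 0 when either endpoint has degree
  ≤ 1 or `z_ij = 0` (the bare-z form, not the z+1 variant, precisely so
  that triangle-free edges score 0).
* **Neighborhood (Czekanowski–Dice) similarity**
  `S_nb(i,j) = 1 − |Int(i) Δ Int(j)| / (|Int(i)| + |Int(j)|)` over closed
  adjacency lists; defined for non-adjacent pairs too.
* **Edge betweenness**: per edge, the number of all-pairs shortest paths
  through it (each unordered pair contributes once; tied shortest paths
  split their unit weight evenly — Brandes accounting), normalized by the
  maximum so at least one edge scores 1.

Modularity uses the k×k edge-fraction matrix: `d_ii` is the fraction of
edges inside cluster i and an inter-cluster edge contributes half its
fraction to each of `d_ij`, `d_ji`, so the matrix sums to 1 and
`Q = Σᵢ (d_ii − aᵢ²)` is exactly 0 for the single-cluster partition — the
anchor that fixes the convention.  Edgeless networks score 0 by
convention.

## Module detection

All four detectors break ties lexicographically on sorted protein
identifiers, so every output is deterministic.

* **HC (Agnes)**: agglomerative clustering of a similarity matrix
  (`S_cc`, zero off-edges, or `S_nb`), merging the most similar cluster
  pair — average linkage (mean over member pairs, the default) or complete
  linkage (minimum) — until `k` clusters remain.
* **NG**: divisive clustering; `s` times, recompute edge betweenness on
  the current graph and remove the single highest-betweenness edge.
  Modules are the connected components.  `s` counts edge removals (the
  monotone reading: step s always refines step s−1).
* **MCL**: adds unit self-loops, column-normalizes, then alternates
  expansion (matrix power 2) and inflation (entrywise power `r`,
  renormalize) until the change drops below 1e−6 or 200 iterations;
  entries below 1e−8 are pruned.  Clusters are read from attractor rows;
  nodes claimed by several attractors go to the lexicographically smallest
  cluster.  Larger `r` gives more, smaller clusters.
* **MCODE**: vertex weight = k of the highest k-core of the vertex's
  closed neighborhood × that core's density; greedy expansion from the
  highest-weight unvisited seed admits neighbors with weight
  > seed_weight·(1 − t); an optional fluff stage (density threshold `f`)
  adds boundary vertices and permits overlap.  Haircut is off by default.
  Modules of size < 2 are discarded; unassigned nodes are reported as a
  residual set, never forced into modules.

Default parameters (`r = 1.4`, `t = 0.2`, `s = 4200`, `k = 350`) are the
best-modularity settings on the yeast corpus the method family was
developed for; on small synthetic benchmarks `k` and `s` should be set
relative to the network (e.g. `k` = number of expected modules).

## Prior-knowledge supervision

The transitive closures of a constraint set are the connected components
of the graph whose edges are the must-link pairs.  Two strategies build on
them:

* **ssHC**: the closures, plus singletons for unconstrained proteins, are
  the initial clusters of the agglomerative merge; since a closure is
  never split, no must-link pair can end up separated.  Closure-to-cluster
  similarity uses the mean over member pairs (missing entries count as 0).
  `k` may not exceed the initial cluster count; the error reports the
  feasible maximum.
* **Two-stage ssNG / ssMCL / ssMCODE**: stage 1 over-splits with relaxed
  parameters (`s = 6500`, `r = 5`, `t = 0.05`); stage 2 builds a
  meta-graph over sub-modules with an edge when at least one constraint
  spans two of them, and merges each meta connected component into one
  module.  One spanning constraint suffices by default (`min_links`
  raises the bar); for overlapping MCODE sub-modules the overlap survives
  the merge.  Merging is purely constraint-driven; it does not require a
  PPI edge between merged sub-modules.

The supervised variants are intended to run on the *augmented* network
(PPI edges ∪ functional pairs) with the same pair set acting as
constraints, and to be compared against the plain method on the raw
network at the same parameters — that is the comparison the evaluation
reproduces.  Applied to a raw noisy network instead, stage-1 MCL tends to
pair noise-linked low-degree vertices into impure two-node sub-modules
whose constraints then chain unrelated modules together; augmentation
densifies true modules and suppresses exactly those attractors.

Cannot-link constraints are accepted in the file format but ignored with
a warning: the framework only uses must-links.

## Evaluation

Enrichment of a module for a catalog complex is the one-sided
hypergeometric tail `P(X ≥ hits)` with population the annotated universe
(default: the catalog universe), successes the complex members and draws
the module's annotated members; zero-hit complexes are skipped.  A
module's enrichment score is −log₁₀ of the geometric mean of its enriched
p-values (equivalently the mean of the individual −log₁₀ p); base 10 is
the default and configurable, and no multiple-testing correction is
applied by default since the headline statistic is the raw −log p of each
module's best complex.  A module counts as "annotated" when its best
p-value is ≤ α (default 0.05); coverage is the fraction of network
proteins inside annotated modules.  Reports list each module's top two
complexes (size, annotated members, complex id, hits).

## Synthetic benchmark

`generate_benchmark` plants modules of two topologies: *cliques* (every
within pair a candidate edge) and *stars* (only hub–leaf pairs; the hub is
the lexicographically first member).  Candidate edges are kept
independently with the retention rate (default 0.9); every inter-module
pair becomes a noise edge independently at the noise rate (default 0.02).
The default benchmark — six modules of ten proteins, alternating clique
and star — is small enough for exhaustive scrutiny yet shows the
phenomenon that motivates supervision: star modules have no triangles, so
density-based detectors (`HC_cc`, MCODE) cannot see them, while
must-links among star leaves make them recoverable.

`generate_constraints` samples within-module pairs independently at
`within_rate` (default 0.6).  `contamination_rate` is the *false fraction*
of the emitted set: `round(rate · n_true)` uniformly drawn cross-module
pairs.  A per-pair false probability would make the expected number of
false links scale with the squared network size and transitively chain
every planted module into one closure — the opposite of what a
high-precision similarity threshold produces — so the false count is tied
to the true count instead.  Even so, false constraints are the binding
failure mode: with only six planted modules, three false pairs typically
chain half of them, capping the achievable agreement of any
constraint-respecting method; closure-seeded hierarchical clustering still
beats its unsupervised counterpart by a wide margin under a 2% false
fraction, but constraint sets for two-stage merging should be
high-precision.

What the generator does *not* emulate: scale-free degree distributions,
overlapping true complexes, annotation bias, or the size heterogeneity of
real complex catalogs.  Passing recovery tests therefore demonstrate the
mechanics of the supervision — constraints are honored, stars become
recoverable, agreement improves — not performance on real interactomes.

Agreement with the planted truth is the adjusted Rand index; overlapping
predictions are resolved by assigning each protein to its largest
containing module (ties lexicographic) and unassigned proteins become
singletons.

## Numerical and degenerate-input choices

* Similarities are clamped to [0, 1]; p-values to (0, 1], with p = 0
  clamped to the smallest positive normal float (warning).
* Terms with zero cumulative frequency have undefined probability and are
  excluded from similarity; a namespace with no annotations yields only
  undefined values (warning).
* MCL non-convergence at 200 iterations returns the current matrix's
  interpretation with a warning; columns are re-normalized after pruning
  so they stay stochastic to 1e−9.
* NG stops early with a warning if asked for more removals than edges.
* Empty inputs: an edgeless network has empty betweenness and zero
  modularity; an empty constraint set yields an empty closure set and
  leaves supervised methods equal to their base methods.

## Problem sizes used in tests

The shipped tests and the acceptance script run on the 60-node default
benchmark (10 seeds), random graphs of ≤ 12 nodes for the brute-force
betweenness oracle (200 instances), enrichment universes of ≤ 20 proteins
for exhaustive subset enumeration, and the 4585-gene identifier list for
the pair-count identity — sizes chosen so every oracle can be exhaustive
and the whole suite runs in seconds.
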