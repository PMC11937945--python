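# Methods

## Model and assumptions

`fibersym` analyzes directed multigraphs in which a node (typically an
enzyme) receives "messages" along typed, multiplicity-weighted incoming
edges (typically: the metabolite a preceding reaction produced).  The
central object is the **input tree** T_i of a node i: the layered rooted
tree of all directed paths terminating at i.  Layer 1 is the root; layer k
holds the start-points of all paths of length k−1, counted with edge
multiplicity.  Under the modeling assumptions — synchronous message
passing, no transmission delays, homogeneous input functions — two nodes
with isomorphic input trees process identical information histories and are
predicted to synchronize.  Maximal groups of such nodes are **fibers**.

Fibers are exactly the classes of the **coarsest balanced coloring**: a
coloring in which two nodes share a color iff their in-edge multisets of
(source color, edge type), counted with multiplicity, are equal.  Collapsing
each fiber to a single node yields the **base** B and a surjective graph
morphism φ: G → B with the lifting property (every edge into an image node
lifts uniquely to an edge into each preimage node).  The base is the
maximal compression of G that preserves every input tree; the package
represents the dynamical statement Dyn(G) = Dyn(B) only through the
lifting-property checker, never by simulating dynamics.

The growth of the layer sums a_i of an input tree is summarized by the
**branching ratio** r = lim a_{i+1}/a_i.  Every directed cycle of length d
backward-reachable from the root contributes a term n·a_{i−d} to the linear
recurrence satisfied by a_i, where n is the product of edge multiplicities
around the cycle (n distinct cycles of the same length act identically); r
is the dominant root of the characteristic polynomial, equivalently the
spectral radius of the backward-reachable adjacency matrix.  Finite trees
(no backward-reachable cycle) are reported with r = 0, pure chains with
r = 1, branching trees with r > 1.  Noninteger r marks a fractal
("Fibonacci") input tree; the simplest case a_i = a_{i−1} + a_{i−2} gives
the golden ratio 1.618.

## Algorithms and numerical choices

**Balanced coloring.**  Partition refinement from the trivial one-class
coloring: each round re-signs every node with (current color, aggregated
in-profile) and relabels canonically by first occurrence over the
lexicographically sorted node list.  The refinement is monotone and reaches
its fixpoint within |V| rounds (asserted).  A `collapse_parallel` flag
merges typed parallel edges into plain multiplicity before refinement, for
analyses that treat metabolite identity as irrelevant; the default keeps
types distinct, because input-tree isomorphism respects link types and the
multi-edge structure is what produces the large observed branching ratios.

**Branching ratio.**  The layer-occupancy vector is iterated backward
through the in-edges with per-step sup-norm normalization (the ratio of
consecutive layer sums is scale-invariant; normalization only prevents
overflow).  Iteration stops when r changes by less than `tol`
(default 1e−9) on **three consecutive** steps — ratio sequences oscillate
around their limit (e.g. the multiplicity-6/6/4 two-node block oscillates
around 8.7446, which is why a first-touch stopping rule can print 8.75) —
or when a layer empties (finite tree), or at `max_iter` (default 10,000,
`converged=False`).  Full precision is kept internally; rounding to 2–3
decimals happens only in reports.  `layer_counts` is exact integer
arithmetic at all depths.  For periodic backward-reachable cycle structures
(e.g. a bare 2-cycle) the ratio sequence genuinely does not converge and
the result is flagged unconverged rather than forced.

**Input-tree isomorphism (oracle).**  Depth-bounded tree equivalence is
decided by level-wise label interning: level-d labels are computed from the
multiset of (edge type, level-(d−1) child label) with multiplicity, with
each distinct class interned as a small integer.  This is linear in
depth × |E| and avoids materializing the exponentially large unfolded
trees.  Depth |V| decides full isomorphism and serves as the independent
oracle for the balanced coloring in the test suite.

**Building blocks.**  The block of a fiber accumulates, by iterative
closure: the fiber; its regulators (external in-neighbors); when any fiber
node reaches a regulator, every node on **all tied shortest**
fiber→regulator paths (path length counts edges; multiplicity affects r,
never membership — so longer cycles through other fibers are excluded,
which is what makes a fiber belong to several blocks); and, for every
regulator inside a nontrivial fiber, that fiber's own block ("stitching").
Stitching is required for composite blocks to carry the correct r: a
feed-forward–regulated fiber inherits the regulating Fibonacci fiber's
branching tree.  r is measured at the lexicographically minimal focal-fiber
member restricted to the induced subgraph.

**Classification.**  Structural conditions drive the taxonomy, not the
integer/noninteger dichotomy alone, because the simplest composite feedback
block has r = 2 exactly.  Single-fiber blocks are `fibonacci_simple` when
both Fibonacci conditions hold — (i) a cycle between the fiber and a
regulator and (ii) a self-loop on that cycle — else `|n,l>` with
n = round(r) (0 for finite trees) and l the number of regulators.
Multi-fiber blocks with a cycle crossing two or more nontrivial fibers are
`composite_feedback_fibonacci`; acyclic compositions are
`composite_feedforward_fibonacci` when r is noninteger (within
`integer_tol`, default 1e−6; r converges to near machine precision on
desk-scale blocks) and `multilayer` otherwise, labeled by the ⊕-joined
per-fiber |n,l> labels (focal fiber first, then by lexicographically
minimal member).  A fiber contained in several blocks is *defined* by the
member-count-smallest one (shortest cycles dominate), ties broken by the
block's minimal member.

**Node roles.**  SCC members are nodes in an SCC of size ≥ 2 or singletons
with a self-loop (a length-1 cycle, consistent with Fibonacci condition
(ii)); connectors are non-SCC nodes with an edge into an SCC; everything
else — including isolated nodes and nodes attached only to shell nodes,
which the role scheme does not otherwise cover — defaults to the k_out
shell.

**Comparators.**  The adjusted Rand index follows the permutation-model
contingency form (delegated to scikit-learn after singleton completion of
partial covers: nodes missing from one grouping become singletons, matching
comparisons of fibers/motif membership against full module partitions).
Directed modularity Q = (1/m) Σ_{u,v} [A_uv − d_u^in d_v^out / m] δ(C_u,C_v)
counts multiplicities in m and in the degrees; Louvain optimization is
delegated to networkx's directed implementation (deterministic per seed)
and the achieved Q is recomputed by this package's own evaluator.  The
motif census counts node *subsets* whose induced simple connectivity
contains the pattern (extra edges allowed; a strict-induced flag is
provided) for the feed-forward loop, bi-fan, bi-parallel and 4-cycle;
self-loops are ignored in matching.  The null model performs
degree-preserving double-edge swaps on the simple view (default 10×|E|
attempted swaps per draw, 1000 draws; neither is canonical, both are
configurable), rejecting swaps that duplicate edges or create self-loops
and keeping existing self-loops fixed as structurally meaningful.  Z-scores
use the ensemble mean and SD; σ = 0 maps to Z = +∞ when the observed count
exceeds the null mean and 0 otherwise; significance means Z > 2.

## Synthetic generators: what they emulate, what they don't

`make_recurrence_block(terms)` realizes any linear layer-count recurrence
a_i = Σ n_d a_{i−d} as a root with one cycle per term (self-loop for d = 1,
chain of d−1 fresh nodes otherwise, one edge carrying the multiplicity n).
`make_planted_fiber_network` plants fibers by giving all members identical
in-neighborhoods drawn from a pool of regulators; regulators carry
pairwise-distinct self-loop multiplicities (≥ 4) and fiber in-neighborhood
signatures are deduplicated and barred from replicating a regulator's own
profile, so the ground truth is provably the exact coarsest balanced
coloring — recovery tests certify the algorithm, not a statistical
tendency.  `make_two_fiber_toy` is the canonical 4-node two-fiber example (two
self-loop-driven components distinguished by edge type).
`make_complexity_ladder` produces the five-step edge-addition sequence from
a chain fiber |1,0> to a composite feedback block, with fibers lifted to
two members and the downstream fiber regulated through a distinct edge
type so that composition is visible to the coloring.

These generators emulate the *structural* conditions of enzyme networks —
typed multi-edges, self-loops, planted symmetry — but not their biological
realism: no reaction stoichiometry, no degree heterogeneity beyond what is
planted, no noise or missing edges (real curation gaps can split or merge
fibers), and no approximate symmetry.  Passing tests therefore certify the
algorithms on exactly symmetric inputs, not robustness of fiber calls on
noisy reconstructions.

## Problem sizes

The test suite and the reproduction script run on desk-scale structures:
two- and three-node recurrence blocks, the 4-node toy, lifted ladders of up
to seven nodes, random multigraphs of up to 12 nodes (200 instances for the
coloring/isomorphism oracle equivalence), random cycle blocks of up to 10
nodes against the spectral oracle, exhaustive motif enumeration up to 9
nodes, planted-fiber networks of up to ~25 nodes across 50 seeds, and
motif null ensembles of 200 draws on a 60-node planted-motif graph.  All
algorithms scale far beyond this (coloring and branching-ratio iteration
are near-linear per round in |E|); the chosen sizes are where the
independent brute-force oracles remain exact.

## Known limitations

* No quasi-fibration / approximate-symmetry detection, and no repair of
  broken symmetries; a single spurious edge can split a fiber.
* The branching-ratio iteration reports `converged=False` on periodic
  backward cycle structures instead of switching to a spectral solver.
* Reaction→network construction treats reactions as written (optional
  global reversal flag); it does not model condition-dependent
  directionality, and ubiquitous-metabolite removal is an explicit
  user-supplied list (`rank_metabolites` assists the choice).
* GO semantic similarity, operon-overlap data and curated E. coli
  subnetwork filtering are out of scope; the partition I/O and the ARI
  operation accept externally supplied files for such comparisons.
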