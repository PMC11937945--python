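"""Input trees: layer sequences, branching ratios, and depth-bounded isomorphism.

The input tree of a node is the layered rooted tree of all directed paths
terminating at that node: layer 1 is the root itself and layer i holds the
start-points of the length-(i-1) paths, counted with edge multiplicity.  The
layer sums a_i grow geometrically in the presence of cycles; their limiting
ratio r = lim a_{i+1}/a_i is the branching ratio of the tree — the dominant
growth rate of path counts, an integer for n-ary trees and a noninteger
(fractal) value for Fibonacci-type blocks.  r equals the spectral radius of
the backward-reachable adjacency matrix whenever the ratio iteration
converges.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .graph_core import DirectedMultigraph

STATUS_FINITE = "finite_tree"
STATUS_CHAIN = "chain"
STATUS_BRANCHING = "branching"

#: tolerance used to call r == 1 a chain
_CHAIN_TOL = 1e-6
#: consecutive tolerance passes required before declaring ratio convergence
_STABLE_STEPS = 3


@dataclass(frozen=True)
class LayerSequence:
    """Exact layer counts a_1, a_2, ... of an input tree and per-layer occupancy.

    ``occurrences[i][u]`` is the number of times original node u appears in
    layer i+1; ``counts[i]`` is its sum, the number of directed paths of
    length i ending at the root (counted with edge multiplicity).  Layers are
    truncated once empty (finite tree).
    """

    root: str
    counts: tuple[int, ...]
    occurrences: tuple[dict[str, int], ...] = field(repr=False)

    def __len__(self) -> int:
        return len(self.counts)


def _step(g: DirectedMultigraph, occ: dict[str, int]) -> dict[str, int]:
    """One backward layer step: new[u] = sum_v mult(u->v) * occ[v]."""
    new: dict[str, int] = {}
    for v, count in occ.items():
        for u, _t, m in g.in_edges(v):
            new[u] = new.get(u, 0) + m * count
    return new


def layer_counts(g: DirectedMultigraph, root: str, depth: int) -> LayerSequence:
    """Exact integer layer counts of *root*'s input tree down to *depth* layers.

    Layer 1 is the indicator of the root (a_1 = 1); layer i+1 occurrence of u
    is ``sum_v multiplicity(u->v) * layer_i(v)``.  Computation stops early
    when a layer becomes empty.
    """
    if root not in g:
        raise KeyError(f"root {root!r} not in graph")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    occ: dict[str, int] = {root: 1}
    occurrences = [dict(occ)]
    counts = [1]
    for _ in range(depth - 1):
        occ = _step(g, occ)
        if not occ:
            break
        occurrences.append(dict(occ))
        counts.append(sum(occ.values()))
    return LayerSequence(root, tuple(counts), tuple(occurrences))


@dataclass(frozen=True)
class BranchingRatio:
    """Limiting ratio of input-tree layer sums with convergence diagnostics.

    ``status`` is ``finite_tree`` (no cycle backward-reachable from the root,
    r reported as 0), ``chain`` (r = 1 within tolerance), or ``branching``
    (r > 1).  ``value`` keeps full float precision; round only for display.
    """

    value: float
    status: str
    iterations: int
    converged: bool

    def rounded(self, ndigits: int = 2) -> float:
        return round(self.value, ndigits)


def branching_ratio(
    g: DirectedMultigraph,
    root: str,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> BranchingRatio:
    """Iterative branching ratio of *root*'s input tree.

    Iterates the layer-occupancy vector with per-step sup-norm normalization
    (the ratio r_i = a_{i+1}/a_i is scale-invariant, so normalization only
    prevents overflow) and stops when r changes by less than *tol* on three
    consecutive iterations, when a layer empties (finite tree, r = 0), or at
    *max_iter* (``converged=False``).
    """
    if root not in g:
        raise KeyError(f"root {root!r} not in graph")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    occ: dict[str, float] = {root: 1.0}
    r_prev: float | None = None
    stable = 0
    for it in range(1, max_iter + 1):
        new: dict[str, float] = {}
        for v, count in occ.items():
            for u, _t, m in g.in_edges(v):
                new[u] = new.get(u, 0.0) + m * count
        s_new = sum(new.values())
        if s_new == 0.0:
            return BranchingRatio(0.0, STATUS_FINITE, it, True)
        r = s_new / sum(occ.values())
        if r_prev is not None and abs(r - r_prev) < tol:
            stable += 1
            if stable >= _STABLE_STEPS:
                status = STATUS_CHAIN if abs(r - 1.0) <= _CHAIN_TOL else STATUS_BRANCHING
                return BranchingRatio(r, status, it, True)
        else:
            stable = 0
        r_prev = r
        peak = max(new.values())
        occ = {u: x / peak for u, x in new.items()}
    status = STATUS_CHAIN if abs(r_prev - 1.0) <= _CHAIN_TOL else STATUS_BRANCHING
    return BranchingRatio(r_prev, status, max_iter, False)


def recurrence_ratio(
    coefficients: list[tuple[int, int]],
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> float:
    """Limiting consecutive-term ratio of ``a_i = sum_d n_d * a_{i-d}``.

    Seeded with a_1 = 1 and absent earlier terms 0; iterated with
    renormalization until the ratio changes by less than *tol* on three
    consecutive steps.  The result equals the dominant root of the
    characteristic polynomial ``x^D = sum_d n_d x^{D-d}``.
    """
    if not coefficients:
        raise ValueError("empty coefficient list")
    coeff: dict[int, int] = {}
    for d, n in coefficients:
        if d < 1 or n < 1:
            raise ValueError(f"lags and coefficients must be >= 1, got ({d}, {n})")
        coeff[d] = coeff.get(d, 0) + n
    maxlag = max(coeff)
    window: list[float] = [0.0] * (maxlag - 1) + [1.0]  # a_1 = 1
    r_prev: float | None = None
    stable = 0
    for _ in range(max_iter):
        nxt = sum(n * window[-d] for d, n in coeff.items())
        # zero terms occur transiently when every lag is even; no ratio then
        r = nxt / window[-1] if window[-1] != 0 else None
        window = window[1:] + [nxt]
        peak = max(abs(x) for x in window)
        if peak > 1e100:
            window = [x / peak for x in window]
        if r is not None and r_prev is not None and abs(r - r_prev) < tol:
            stable += 1
            if stable >= _STABLE_STEPS:
                return r
        else:
            stable = 0
        r_prev = r
    return r_prev


def _tree_labels(g: DirectedMultigraph, depth: int) -> dict[str, int]:
    """Interned isomorphism labels of every node's depth-bounded input tree.

    Level d labels are computed from level d-1: two nodes get the same label
    iff the multisets of (edge type, level-(d-1) child label), counted with
    multiplicity, coincide.  Interning subtree classes as small integers
    keeps the comparison linear in depth * |E| instead of materializing the
    (exponentially large) unfolded trees.
    """
    labels = {n: 0 for n in g.nodes}  # depth 0: every tree is a bare root
    for _ in range(depth):
        table: dict[tuple, int] = {}
        new: dict[str, int] = {}
        for n in g.nodes:
            agg: dict[tuple[str, int], int] = {}
            for u, t, m in g.in_edges(n):
                key = (t, labels[u])
                agg[key] = agg.get(key, 0) + m
            sig = tuple(sorted((t, lab, m) for (t, lab), m in agg.items()))
            if sig not in table:
                table[sig] = len(table)
            new[n] = table[sig]
        labels = new
    return labels


def input_tree_isomorphic(
    g: DirectedMultigraph, u: str, v: str, depth: int
) -> bool:
    """Depth-bounded input-tree isomorphism.

    Two trees match at depth d iff the multisets of (edge type, child subtree
    at depth d-1) over in-edges, counted with multiplicity, match.  Comparing
    at depth |V| decides full isomorphism (the refinement stabilizes within
    |V| levels), which is the brute-force oracle for balanced coloring.
    """
    if u not in g or v not in g:
        raise KeyError(f"nodes {u!r}, {v!r} must be in the graph")
    if depth < 0:
        raise ValueError("depth must be >= 0")
    labels = _tree_labels(g, depth)
    return labels[u] == labels[v]
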