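"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import math
from itertools import combinations, permutations, product

import numpy as np
import pytest

from fibersym import DirectedMultigraph


# -- random fixtures ---------------------------------------------------------


def random_multigraph(
    rng: np.random.Generator,
    n_nodes: int,
    edge_prob: float = 0.25,
    n_types: int = 2,
    max_mult: int = 2,
    self_loops: bool = True,
) -> DirectedMultigraph:
    """Seeded random typed multigraph on nodes n00..n{k}."""
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    g = DirectedMultigraph()
    for n in nodes:
        g.add_node(n)
    for u in nodes:
        for v in nodes:
            if u == v and not self_loops:
                continue
            if rng.random() < edge_prob:
                t = f"t{rng.integers(n_types)}"
                m = int(rng.integers(1, max_mult + 1))
                g.add_edge(u, v, t, m)
    return g


@pytest.fixture
def rng():
    return np.random.default_rng(20_240_317)


# -- independent oracles -----------------------------------------------------


def brute_force_sccs(g: DirectedMultigraph) -> list[set[str]]:
    """SCCs by pairwise mutual reachability (transitive closure by iteration)."""
    nodes = g.nodes
    reach = {u: {u} | g.successors(u) for u in nodes}
    changed = True
    while changed:
        changed = False
        for u in nodes:
            extra = set().union(*(reach[v] for v in reach[u]))
            if not extra <= reach[u]:
                reach[u] |= extra
                changed = True
    sccs: list[set[str]] = []
    seen: set[str] = set()
    for u in nodes:
        if u in seen:
            continue
        comp = {v for v in nodes if u in reach[v] and v in reach[u]}
        sccs.append(comp)
        seen |= comp
    sccs.sort(key=lambda c: (-len(c), min(c)))
    return sccs


def ari_from_contingency(x_groups, y_groups) -> float:
    """Adjusted Rand index evaluated directly on the contingency table."""
    x_groups = [set(s) for s in x_groups]
    y_groups = [set(s) for s in y_groups]
    n = sum(len(s) for s in x_groups)
    nij = [[len(xi & yj) for yj in y_groups] for xi in x_groups]
    a = [sum(row) for row in nij]
    b = [sum(col) for col in zip(*nij)]
    sum_ij = sum(math.comb(v, 2) for row in nij for v in row)
    sum_a = sum(math.comb(v, 2) for v in a)
    sum_b = sum(math.comb(v, 2) for v in b)
    expected = sum_a * sum_b / math.comb(n, 2)
    max_index = (sum_a + sum_b) / 2
    if max_index == expected:
        return 1.0 if sum_ij == max_index else 0.0
    return (sum_ij - expected) / (max_index - expected)


def directed_modularity_by_communities(g: DirectedMultigraph, labels: dict) -> float:
    """Q evaluated at the community level: (1/m) sum_C [E_CC - d^in_C d^out_C / m]."""
    m = g.total_multiplicity()
    comms = sorted(set(labels.values()), key=str)
    q = 0.0
    for c in comms:
        members = {n for n, l in labels.items() if l == c}
        e_cc = sum(w for u, v, _t, w in g.edges() if u in members and v in members)
        din = sum(w for _u, v, _t, w in g.edges() if v in members)
        dout = sum(w for u, _v, _t, w in g.edges() if u in members)
        q += e_cc - din * dout / m
    return q / m


def best_modularity_exhaustive(g: DirectedMultigraph) -> float:
    """Maximum directed modularity by exhaustive partition search (<= 8 nodes)."""
    nodes = g.nodes
    assert len(nodes) <= 8

    def partitions(items):
        if not items:
            yield []
            return
        first, rest = items[0], items[1:]
        for smaller in partitions(rest):
            for i, block in enumerate(smaller):
                yield smaller[:i] + [block + [first]] + smaller[i + 1 :]
            yield smaller + [[first]]

    best = -math.inf
    for part in partitions(nodes):
        labels = {n: i for i, block in enumerate(part) for n in block}
        best = max(best, directed_modularity_by_communities(g, labels))
    return best


_MOTIF_PATTERNS = {
    "feed_forward_loop": ((0, 1), (0, 2), (1, 2)),
    "bifan": ((0, 2), (0, 3), (1, 2), (1, 3)),
    "biparallel": ((0, 1), (0, 2), (1, 3), (2, 3)),
    "cycle4": ((0, 1), (1, 2), (2, 3), (3, 0)),
}


def exhaustive_motif_counts(g: DirectedMultigraph, induced: bool = False) -> dict[str, int]:
    """Motif counts by enumerating every node subset and role permutation."""
    edges = {(u, v) for (u, v, _t, _m) in g.edges() if u != v}
    nodes = g.nodes
    counts = {m: 0 for m in _MOTIF_PATTERNS}
    for motif, pattern in _MOTIF_PATTERNS.items():
        k = max(max(p) for p in pattern) + 1
        for subset in combinations(nodes, k):
            present = {
                (i, j)
                for (i, u), (j, v) in product(enumerate(subset), enumerate(subset))
                if i != j and (u, v) in edges
            }
            ok = False
            for perm in permutations(range(k)):
                mapped = {(perm[i], perm[j]) for i, j in present}
                if induced:
                    ok = mapped == set(pattern)
                else:
                    ok = set(pattern) <= mapped
                if ok:
                    break
            counts[motif] += ok
    return counts


def spectral_radius_backward(g: DirectedMultigraph, root: str) -> float:
    """Spectral radius of the multiplicity matrix on the backward-reachable set."""
    reach = {root}
    frontier = [root]
    while frontier:
        nxt = []
        for v in frontier:
            for u in g.predecessors(v):
                if u not in reach:
                    reach.add(u)
                    nxt.append(u)
        frontier = nxt
    nodes = sorted(reach)
    idx = {n: i for i, n in enumerate(nodes)}
    a = np.zeros((len(nodes), len(nodes)))
    for u, v, _t, m in g.edges():
        if u in reach and v in reach:
            a[idx[u], idx[v]] += m
    return float(max(abs(np.linalg.eigvals(a)))) if len(nodes) else 0.0
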