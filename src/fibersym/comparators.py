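"""Benchmarks against fiber partitions: ARI, directed modularity, motifs.

Three classic yardsticks for node groupings in directed networks:

* the adjusted Rand index under the permutation model, used to compare a
  fiber partition with module partitions or motif-membership groupings
  (partial covers are completed with singletons first);
* directed modularity Q = (1/m) * sum_{u,v} [A_uv - d_u^in d_v^out / m]
  delta(C_u, C_v), optimized by the greedy Louvain procedure;
* a census of the classic 3/4-node motifs (feed-forward loop, bi-fan,
  bi-parallel, 4-cycle) with Z-scores against a degree-preserving
  randomized ensemble; a motif is significant when Z > 2.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass
from itertools import combinations

import networkx as nx
import numpy as np
from sklearn.metrics import adjusted_rand_score

from .graph_core import DirectedMultigraph

Grouping = dict[str, object] | list  # node -> group id, or list of node sets


def _as_labels(grouping) -> dict[str, object]:
    if isinstance(grouping, dict):
        return {str(k): v for k, v in grouping.items()}
    labels: dict[str, object] = {}
    for i, group in enumerate(grouping):
        for node in group:
            if node in labels:
                raise ValueError(f"node {node!r} appears in two groups")
            labels[str(node)] = i
    return labels


def adjusted_rand_index(
    x: Grouping, y: Grouping, complete_universe: bool = True
) -> float:
    """Adjusted Rand index (permutation model) between two groupings.

    Accepts node->group mappings or lists of node sets.  With
    ``complete_universe=True`` (default) nodes present in only one grouping
    are placed in their own singleton groups first, mirroring comparisons of
    partial covers (fibers, motif membership) against full partitions
    (modules); otherwise mismatched universes are an error.  Returns 1.0 for
    identical partitions and approximately 0 in expectation for independent
    ones.
    """
    lx, ly = _as_labels(x), _as_labels(y)
    universe = set(lx) | set(ly)
    if not universe:
        raise ValueError("empty node universe")
    if not complete_universe and set(lx) != set(ly):
        raise ValueError("groupings cover different node sets")
    nodes = sorted(universe)
    # singleton-completion: unseen nodes get unique labels
    a = [("g", lx[n]) if n in lx else ("s", n) for n in nodes]
    b = [("g", ly[n]) if n in ly else ("s", n) for n in nodes]
    ax = {v: i for i, v in enumerate(dict.fromkeys(a))}
    bx = {v: i for i, v in enumerate(dict.fromkeys(b))}
    return float(adjusted_rand_score([ax[v] for v in a], [bx[v] for v in b]))


def directed_modularity(g: DirectedMultigraph, partition: Grouping) -> float:
    """Directed modularity Q of a community partition (multiplicities as weights)."""
    labels = _as_labels(partition)
    if set(labels) != set(g.nodes):
        raise ValueError("partition does not cover the node set")
    m = g.total_multiplicity()
    if m < 1:
        raise ValueError("modularity undefined for an edgeless graph")
    din: dict[str, int] = {n: 0 for n in g.nodes}
    dout: dict[str, int] = {n: 0 for n in g.nodes}
    internal = 0
    for u, v, _t, w in g.edges():
        dout[u] += w
        din[v] += w
        if labels[u] == labels[v]:
            internal += w
    null = 0.0
    by_comm: dict[object, list[str]] = {}
    for n, c in labels.items():
        by_comm.setdefault(c, []).append(n)
    for nodes in by_comm.values():
        sin = sum(din[n] for n in nodes)
        sout = sum(dout[n] for n in nodes)
        null += sin * sout / m
    return (internal - null) / m


@dataclass(frozen=True)
class ModulePartition:
    """Community labels plus the achieved directed modularity Q."""

    labels: dict[str, int]
    q: float

    def groups(self) -> list[frozenset[str]]:
        by: dict[int, set[str]] = {}
        for n, c in self.labels.items():
            by.setdefault(c, set()).add(n)
        return [frozenset(by[c]) for c in sorted(by)]


def louvain_partition(g: DirectedMultigraph, seed: int = 0) -> ModulePartition:
    """Greedy Louvain maximization of directed modularity (deterministic per seed)."""
    if g.total_multiplicity() < 1:
        raise ValueError("Louvain clustering requires at least one edge")
    nxg = g.to_simple_digraph(weighted=True)
    communities = nx.community.louvain_communities(nxg, weight="weight", seed=seed)
    labels = {n: i for i, c in enumerate(sorted(communities, key=min)) for n in c}
    q = directed_modularity(g, labels)
    return ModulePartition(labels, q)


# -- motif census ------------------------------------------------------------

MOTIFS = ("feed_forward_loop", "bifan", "biparallel", "cycle4")

#: motif edge patterns on role-numbered nodes 0..k-1
_MOTIF_EDGES = {
    "feed_forward_loop": ((0, 1), (0, 2), (1, 2)),
    "bifan": ((0, 2), (0, 3), (1, 2), (1, 3)),
    "biparallel": ((0, 1), (0, 2), (1, 3), (2, 3)),
    "cycle4": ((0, 1), (1, 2), (2, 3), (3, 0)),
}


def _simple_edge_set(g: DirectedMultigraph) -> tuple[set[tuple[str, str]], list[str]]:
    edges = {(u, v) for (u, v, _t, _m) in g.edges() if u != v}
    return edges, g.nodes


def motif_census(g: DirectedMultigraph, induced: bool = False) -> dict[str, int]:
    """Count node subsets realizing each 3/4-node motif.

    A subset counts once when some role assignment places all motif edges in
    its induced (simple, self-loop-free) connectivity; extra edges are
    allowed unless ``induced=True``, which requires the induced edge set to
    equal the motif pattern exactly.
    """
    edges, _nodes = _simple_edge_set(g)
    succ: dict[str, set[str]] = {}
    pred: dict[str, set[str]] = {}
    for u, v in edges:
        succ.setdefault(u, set()).add(v)
        pred.setdefault(v, set()).add(u)
    counts = {m: 0 for m in MOTIFS}

    def induced_size(subset: tuple[str, ...]) -> int:
        s = set(subset)
        return sum(1 for u in s for v in succ.get(u, ()) if v in s)

    # feed-forward loop: a->b, a->c, b->c
    ffl: set[frozenset[str]] = set()
    for b, c in edges:
        for a in pred.get(b, set()) & pred.get(c, set()):
            if a not in (b, c):
                ffl.add(frozenset((a, b, c)))
    if induced:
        ffl = {s for s in ffl if induced_size(tuple(s)) == 3 and _matches_exact(s, "feed_forward_loop", succ)}
    counts["feed_forward_loop"] = len(ffl)

    # bifan: a->c, a->d, b->c, b->d
    bifan: set[frozenset[str]] = set()
    sources = sorted(succ)
    for a, b in combinations(sources, 2):
        common = (succ[a] & succ[b]) - {a, b}
        for c, d in combinations(sorted(common), 2):
            bifan.add(frozenset((a, b, c, d)))
    if induced:
        bifan = {s for s in bifan if _matches_exact(s, "bifan", succ)}
    counts["bifan"] = len(bifan)

    # biparallel: a->b, a->c, b->d, c->d
    bipar: set[frozenset[str]] = set()
    for a in sorted(succ):
        for d in sorted(pred):
            if a == d:
                continue
            mid = (succ[a] & pred[d]) - {a, d}
            for b, c in combinations(sorted(mid), 2):
                bipar.add(frozenset((a, b, c, d)))
    if induced:
        bipar = {s for s in bipar if _matches_exact(s, "biparallel", succ)}
    counts["biparallel"] = len(bipar)

    # 4-cycle: a->b->c->d->a
    cyc: set[frozenset[str]] = set()
    for a in sorted(succ):
        for b in succ[a]:
            if b == a:
                continue
            for c in succ.get(b, ()):  # pragma: no branch
                if c in (a, b):
                    continue
                for d in succ.get(c, ()):
                    if d in (a, b, c):
                        continue
                    if a in succ.get(d, ()):
                        cyc.add(frozenset((a, b, c, d)))
    if induced:
        cyc = {s for s in cyc if _matches_exact(s, "cycle4", succ)}
    counts["cycle4"] = len(cyc)
    return counts


def _matches_exact(subset: frozenset[str], motif: str, succ: dict[str, set[str]]) -> bool:
    """Strict-induced check: some role assignment makes the induced edges equal the pattern."""
    from itertools import permutations

    pattern = set(_MOTIF_EDGES[motif])
    nodes = sorted(subset)
    present = {
        (i, j)
        for i, u in enumerate(nodes)
        for j, v in enumerate(nodes)
        if i != j and v in succ.get(u, ())
    }
    if len(present) != len(pattern):
        return False
    k = len(nodes)
    for perm in permutations(range(k)):
        if {(perm[i], perm[j]) for i, j in present} == pattern:
            return True
    return False


def degree_preserving_randomize(
    g: DirectedMultigraph, n_swaps: int, seed: int
) -> DirectedMultigraph:
    """Degree-preserving double-edge-swap randomization of the simple view.

    Attempts *n_swaps* swaps of directed edge pairs (a->b, c->d) => (a->d,
    c->b); swaps that would duplicate an existing edge or create a self-loop
    are rejected.  Self-loops of the input are structurally meaningful and
    are preserved unswapped.  In- and out-degree sequences of the simple
    view are conserved exactly.
    """
    rng = random.Random(seed)
    edges, _nodes = _simple_edge_set(g)
    edge_list = sorted(edges)
    if len(edge_list) >= 2:
        edge_set = set(edge_list)
        for _ in range(n_swaps):
            i, j = rng.randrange(len(edge_list)), rng.randrange(len(edge_list))
            if i == j:
                continue
            a, b = edge_list[i]
            c, d = edge_list[j]
            if a == d or c == b:
                continue  # would create a self-loop
            if (a, d) in edge_set or (c, b) in edge_set:
                continue  # would duplicate an edge
            edge_set.discard((a, b))
            edge_set.discard((c, d))
            edge_set.add((a, d))
            edge_set.add((c, b))
            edge_list[i] = (a, d)
            edge_list[j] = (c, b)
    out = DirectedMultigraph()
    for n in g.nodes:
        out.add_node(n)
    for u, v in sorted(edge_set if len(edge_list) >= 2 else edges):
        out.add_edge(u, v)
    for n in g.nodes:  # preserved self-loops
        if g.has_self_loop(n):
            out.add_edge(n, n)
    return out


@dataclass(frozen=True)
class MotifCensus:
    """Observed counts, null mean/SD, Z-scores and significance per motif."""

    observed: dict[str, int]
    null_mean: dict[str, float]
    null_sd: dict[str, float]
    zscores: dict[str, float]
    significant: dict[str, bool]
    n_random: int

    def to_rows(self) -> list[dict]:
        return [
            {
                "motif": m,
                "observed": self.observed[m],
                "null_mean": self.null_mean[m],
                "null_sd": self.null_sd[m],
                "z": self.zscores[m],
                "significant": self.significant[m],
            }
            for m in MOTIFS
        ]


def motif_zscores(
    g: DirectedMultigraph,
    n_random: int = 1000,
    n_swaps: int | None = None,
    seed: int = 0,
    induced: bool = False,
) -> MotifCensus:
    """Motif Z-scores against a degree-preserving randomized ensemble.

    ``Z_i = (N_i - <N_i>) / sigma_i`` over *n_random* randomized draws;
    *n_swaps* defaults to 10x the number of simple edges per draw.  When
    sigma_i = 0, Z is +inf if the observed count exceeds the null mean and 0
    otherwise.  A motif is significant when Z > 2.
    """
    if n_random < 2:
        raise ValueError("n_random must be >= 2")
    edges, _ = _simple_edge_set(g)
    if n_swaps is None:
        n_swaps = 10 * len(edges)
    observed = motif_census(g, induced=induced)
    null_counts = {m: [] for m in MOTIFS}
    for k in range(n_random):
        rnd = degree_preserving_randomize(g, n_swaps, seed=seed * 1_000_003 + k)
        cc = motif_census(rnd, induced=induced)
        for m in MOTIFS:
            null_counts[m].append(cc[m])
    mean = {m: float(np.mean(null_counts[m])) for m in MOTIFS}
    sd = {m: float(np.std(null_counts[m])) for m in MOTIFS}
    z: dict[str, float] = {}
    for m in MOTIFS:
        if sd[m] == 0.0:
            z[m] = math.inf if observed[m] > mean[m] else 0.0
        else:
            z[m] = (observed[m] - mean[m]) / sd[m]
    sig = {m: z[m] > 2 for m in MOTIFS}
    return MotifCensus(observed, mean, sd, z, sig, n_random)
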