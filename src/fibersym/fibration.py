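"""Minimal balanced coloring, fiber partitions, and the quotient base graph.

A coloring of a directed multigraph is *balanced* when any two same-colored
nodes receive identical multisets of (source color, edge type), counted with
multiplicity.  The coarsest balanced coloring is computed by partition
refinement from the trivial one-class coloring; its color classes are the
fibers — maximal sets of nodes with isomorphic input trees.  Collapsing each
fiber to one node yields the base graph B with the surjective morphism
phi: G -> B satisfying the lifting property: every edge into an image node
lifts uniquely to an edge into each preimage node, so the base preserves
every node's input tree and is the maximal symmetry-preserving compression
of G.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable

from .graph_core import DirectedMultigraph


@dataclass(frozen=True)
class Coloring:
    """A total node -> color-id map with canonical ids.

    Color ids are small integers assigned by first occurrence over the
    lexicographically sorted node list, so equal partitions always produce
    equal colorings.
    """

    colors: dict[str, int]

    def classes(self) -> list[frozenset[str]]:
        by_color: dict[int, set[str]] = {}
        for node, c in self.colors.items():
            by_color.setdefault(c, set()).add(node)
        return [frozenset(by_color[c]) for c in sorted(by_color)]

    def n_colors(self) -> int:
        return len(set(self.colors.values()))


@dataclass(frozen=True)
class FiberPartition:
    """Disjoint node groups with isomorphic input trees, covering the node set.

    Fibers are ordered by decreasing size then lexicographic minimum member;
    a fiber is *trivial* when it is a singleton.
    """

    fibers: tuple[frozenset[str], ...]

    def __post_init__(self):
        seen: set[str] = set()
        for f in self.fibers:
            if seen & f:
                raise ValueError("fibers must be disjoint")
            seen |= f

    def __len__(self) -> int:
        return len(self.fibers)

    def __iter__(self):
        return iter(self.fibers)

    @property
    def nodes(self) -> set[str]:
        return set().union(*self.fibers) if self.fibers else set()

    def is_trivial(self, i: int) -> bool:
        return len(self.fibers[i]) == 1

    def nontrivial_fibers(self) -> list[frozenset[str]]:
        return [f for f in self.fibers if len(f) >= 2]

    def fiber_of(self, node: str) -> frozenset[str]:
        for f in self.fibers:
            if node in f:
                return f
        raise KeyError(node)

    def class_index(self) -> dict[str, int]:
        return {n: i for i, f in enumerate(self.fibers) for n in f}

    @classmethod
    def from_groups(cls, groups: Iterable[Iterable[str]]) -> "FiberPartition":
        fs = sorted((frozenset(g) for g in groups), key=lambda f: (-len(f), min(f)))
        return cls(tuple(fs))

    def summary(self) -> dict:
        """Per-fiber members/size/trivial flag plus the two fiber counts."""
        return {
            "n_fibers_total": len(self.fibers),
            "n_fibers_nontrivial": len(self.nontrivial_fibers()),
            "fibers": [
                {"members": sorted(f), "size": len(f), "trivial": len(f) == 1}
                for f in self.fibers
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.summary(), indent=2)


def _in_profile(
    g: DirectedMultigraph, node: str, color: dict[str, int]
) -> tuple[tuple[int, str, int], ...]:
    """Aggregated in-edge multiset of (source color, edge type) -> multiplicity."""
    agg: dict[tuple[int, str], int] = {}
    for u, t, m in g.in_edges(node):
        key = (color[u], t)
        agg[key] = agg.get(key, 0) + m
    return tuple(sorted((c, t, m) for (c, t), m in agg.items()))


def _canonical_relabel(g: DirectedMultigraph, raw: dict[str, object]) -> dict[str, int]:
    ids: dict[object, int] = {}
    out: dict[str, int] = {}
    for n in g.nodes:
        key = raw[n]
        if key not in ids:
            ids[key] = len(ids)
        out[n] = ids[key]
    return out


def minimal_balanced_coloring(
    g: DirectedMultigraph, collapse_parallel: bool = False
) -> Coloring:
    """Coarsest balanced coloring of *g* by iterative in-profile refinement.

    Starts from a single color and splits classes by their typed,
    multiplicity-counted in-profile over current colors until a fixpoint;
    terminates within |V| rounds.  ``collapse_parallel=True`` first merges
    typed parallel edges into plain multiplicity, for analyses that treat
    metabolite identity on links as irrelevant.
    """
    if collapse_parallel:
        g = g.collapse_parallel()
    nodes = g.nodes
    if not nodes:
        return Coloring({})
    color = {n: 0 for n in nodes}
    n_colors = 1
    for _round in range(len(nodes) + 1):
        raw = {n: (color[n], _in_profile(g, n, color)) for n in nodes}
        new = _canonical_relabel(g, raw)
        new_n = len(set(new.values()))
        if new_n == n_colors:
            return Coloring(new)
        color, n_colors = new, new_n
    raise AssertionError("balanced-coloring refinement exceeded the |V| round bound")


def is_balanced(
    g: DirectedMultigraph, p: FiberPartition
) -> tuple[bool, tuple[str, str] | None]:
    """Check the balance condition; on failure return a witness node pair.

    True iff every two same-fiber nodes have equal in-profiles over fiber
    classes (typed, counted with multiplicity).
    """
    if p.nodes != set(g.nodes):
        raise ValueError("partition does not cover the graph's node set")
    cls = p.class_index()
    for f in p.fibers:
        members = sorted(f)
        ref = _in_profile(g, members[0], cls)
        for other in members[1:]:
            if _in_profile(g, other, cls) != ref:
                return False, (members[0], other)
    return True, None


def fibers(g: DirectedMultigraph, c: Coloring) -> FiberPartition:
    """Fiber partition from a balanced coloring (one fiber per color class)."""
    p = FiberPartition.from_groups(c.classes())
    ok, witness = is_balanced(g, p)
    if not ok:
        raise ValueError(f"coloring is not balanced; witness pair {witness}")
    return p


def find_fibers(g: DirectedMultigraph, collapse_parallel: bool = False) -> FiberPartition:
    """Convenience: minimal balanced coloring followed by fiber extraction."""
    if collapse_parallel:
        g = g.collapse_parallel()
    return fibers(g, minimal_balanced_coloring(g))


@dataclass(frozen=True)
class BaseGraph:
    """Quotient of a graph by a balanced partition, with phi: node -> base node.

    Base nodes are named after the lexicographically minimal member of their
    fiber.  Each base node's in-edge multiset equals the phi-mapped in-edge
    multiset of any member of its fiber (the lifting property).
    """

    graph: DirectedMultigraph
    phi: dict[str, str]

    def check_lifting(self, original: DirectedMultigraph) -> bool:
        """Verify the lifting property against the original graph."""
        for node in original.nodes:
            agg: dict[tuple[str, str], int] = {}
            for u, t, m in original.in_edges(node):
                key = (self.phi[u], t)
                agg[key] = agg.get(key, 0) + m
            mapped = sorted((u, t, m) for (u, t), m in agg.items())
            base_in = sorted(self.graph.in_edges(self.phi[node]))
            if mapped != base_in:
                return False
        return True


def build_base(g: DirectedMultigraph, p: FiberPartition) -> BaseGraph:
    """Collapse each fiber into one representative node.

    The base in-edges of a fiber are the in-edges of its lexicographically
    minimal member with sources mapped through phi; by balance the member
    choice is immaterial (rejects unbalanced partitions).
    """
    ok, witness = is_balanced(g, p)
    if not ok:
        raise ValueError(f"partition is not balanced; witness pair {witness}")
    phi = {n: min(f) for f in p.fibers for n in f}
    base = DirectedMultigraph()
    for f in p.fibers:
        rep = min(f)
        base.add_node(rep)
        agg: dict[tuple[str, str], int] = {}
        for u, t, m in g.in_edges(rep):
            key = (phi[u], t)
            agg[key] = agg.get(key, 0) + m
        for (u, t), m in sorted(agg.items()):
            base.add_edge(u, rep, t, m)
    result = BaseGraph(base, phi)
    assert result.check_lifting(g), "lifting property violated for a balanced partition"
    return result


def write_partition(p: FiberPartition, path) -> None:
    """Write a two-column TSV (node, fiber_id); fiber ids follow partition order."""
    lines = ["node\tfiber_id"]
    for i, f in enumerate(p.fibers):
        for n in sorted(f):
            lines.append(f"{n}\t{i}")
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def read_partition(path) -> FiberPartition:
    """Read a two-column TSV (node, group id) into a FiberPartition."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"partition file {path} needs two columns (node, group)")
    node_col, group_col = df.columns[:2]
    groups: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        groups.setdefault(str(row[group_col]), set()).add(str(row[node_col]))
    return FiberPartition.from_groups(groups.values())
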