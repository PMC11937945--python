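"""Fibration building blocks: extraction and taxonomic classification.

The building block of a fiber is the induced subgraph on the fiber, its
regulators (external in-neighbors), and — when the fiber sends information
back to a regulator — every node on all shortest fiber-to-regulator paths.
When a regulator itself belongs to a nontrivial fiber, that fiber's own
building block is stitched in, because the regulated fiber's input tree
contains the regulating fiber's input tree.

Blocks are classified into the taxonomy observed in enzyme networks:

* ``n_l``: simple blocks labeled by fiber numbers |n,l> — n is the integer
  branching ratio of the internal cycle structure (0 = finite feed-forward
  tree, 1 = chain) and l the number of external regulators;
* ``fibonacci_simple``: a single fiber with a fiber->regulator feedback
  cycle and a self-loop on that cycle, giving a fractal (usually
  noninteger) branching ratio;
* ``multilayer``: two or more fibers composed feed-forward with integer
  ratios, labeled e.g. ``|0,3>(+)|0,1>``;
* ``composite_feedforward_fibonacci``: a fiber regulated feed-forward by a
  Fibonacci fiber, inheriting its branching ratio;
* ``composite_feedback_fibonacci``: a feedback cycle crossing two or more
  fibers (each fiber acts as a regulator of the other).

Classification is structural: the Fibonacci families are decided by cycle
conditions, not by whether r happens to round to an integer (the simplest
composite feedback block has r = 2 exactly).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import networkx as nx

from .fibration import FiberPartition
from .graph_core import DirectedMultigraph
from .input_tree import (
    STATUS_FINITE,
    BranchingRatio,
    branching_ratio,
)

FAMILY_NL = "n_l"
FAMILY_FIBONACCI = "fibonacci_simple"
FAMILY_MULTILAYER = "multilayer"
FAMILY_COMPOSITE_FF = "composite_feedforward_fibonacci"
FAMILY_COMPOSITE_FB = "composite_feedback_fibonacci"


@dataclass(frozen=True)
class BuildingBlock:
    """Induced subgraph around a fiber, with its regulators and branching ratio."""

    focal_fiber: frozenset[str]
    regulators: frozenset[str]
    members: frozenset[str]
    subgraph: DirectedMultigraph
    branching: BranchingRatio
    root: str

    def __post_init__(self):
        assert not (self.regulators & self.focal_fiber)
        assert self.focal_fiber | self.regulators <= self.members


@dataclass(frozen=True)
class BlockClass:
    """Taxonomic label of a building block."""

    family: str
    n: int | None
    l: int | None
    r: float
    n_fibers_involved: int
    label: str


def _resolve_fiber(p: FiberPartition, fiber_id) -> frozenset[str]:
    if isinstance(fiber_id, int):
        try:
            return p.fibers[fiber_id]
        except IndexError:
            raise KeyError(f"no fiber with index {fiber_id}") from None
    if isinstance(fiber_id, (set, frozenset)):
        f = frozenset(fiber_id)
        if f in p.fibers:
            return f
        raise KeyError(f"no fiber equal to {sorted(f)}")
    try:
        return p.fiber_of(str(fiber_id))
    except KeyError:
        raise KeyError(f"unknown fiber id {fiber_id!r}") from None


def _regulators_of(g: DirectedMultigraph, fiber: frozenset[str]) -> set[str]:
    return {u for v in fiber for u in g.predecessors(v)} - set(fiber)


def _shortest_path_nodes(simple: nx.DiGraph, source: str, target: str) -> set[str]:
    """Nodes on ALL shortest source->target paths (edge-count length)."""
    try:
        dist_fwd = nx.single_source_shortest_path_length(simple, source)
    except nx.NodeNotFound:  # pragma: no cover
        return set()
    if target not in dist_fwd:
        return set()
    dist_bwd = nx.single_source_shortest_path_length(simple.reverse(copy=False), target)
    total = dist_fwd[target]
    return {
        w
        for w in dist_fwd
        if w in dist_bwd and dist_fwd[w] + dist_bwd[w] == total
    }


def extract_block(
    g: DirectedMultigraph,
    p: FiberPartition,
    fiber_id,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> BuildingBlock:
    """Extract the fibration building block of a fiber.

    Members accumulate by iterative closure: the fiber, its regulators,
    all nodes on all shortest (fiber node -> regulator) paths in the parent
    graph when any such feedback path exists, and — for every regulator that
    belongs to a nontrivial fiber — that fiber's own building block.  Path
    length counts edges; multiplicities affect r, never membership.  The
    branching ratio is computed at the lexicographically minimal focal-fiber
    member restricted to the induced subgraph.
    """
    focal = _resolve_fiber(p, fiber_id)
    simple = g.to_simple_digraph()
    members: set[str] = set()
    focal_regulators: frozenset[str] | None = None
    absorbed: set[frozenset[str]] = set()
    queue: list[frozenset[str]] = [focal]
    while queue:
        fiber = queue.pop(0)
        if fiber in absorbed:
            continue
        absorbed.add(fiber)
        members |= fiber
        regs = _regulators_of(g, fiber)
        members |= regs
        if fiber == focal:
            focal_regulators = frozenset(regs)
        for f_node in fiber:
            for reg in regs:
                members |= _shortest_path_nodes(simple, f_node, reg)
        for reg in sorted(regs):
            reg_fiber = p.fiber_of(reg)
            if len(reg_fiber) >= 2 and reg_fiber not in absorbed:
                queue.append(reg_fiber)
    sub = g.subgraph(members)
    root = min(focal)
    br = branching_ratio(sub, root, tol=tol, max_iter=max_iter)
    return BuildingBlock(
        focal_fiber=focal,
        regulators=focal_regulators,
        members=frozenset(members),
        subgraph=sub,
        branching=br,
        root=root,
    )


def _contained_nontrivial_fibers(
    b: BuildingBlock, p: FiberPartition
) -> list[frozenset[str]]:
    return [f for f in p.nontrivial_fibers() if f <= b.members]


def _has_interfiber_cycle(
    b: BuildingBlock, fibers_in_block: list[frozenset[str]]
) -> bool:
    """True when some cycle of the block visits two or more nontrivial fibers."""
    if len(fibers_in_block) < 2:
        return False
    fiber_of = {n: i for i, f in enumerate(fibers_in_block) for n in f}
    simple = b.subgraph.to_simple_digraph()
    for scc in nx.strongly_connected_components(simple):
        touched = {fiber_of[n] for n in scc if n in fiber_of}
        if len(touched) >= 2:
            return True
    return False


def fibonacci_conditions(b: BuildingBlock) -> tuple[bool, bool]:
    """The two structural conditions for a fractal (branching) input tree.

    (i) a cycle between the focal fiber and at least one of its regulators
    (the fiber sends feedback to a regulator and receives it back);
    (ii) a self-loop on any node of that cycle.  When no fiber-regulator
    cycle exists, (ii) reports whether any block member carries a self-loop
    (a cycle of length 1 in its own right).
    """
    simple = b.subgraph.to_simple_digraph()
    cycle_nodes: set[str] = set()
    has_cycle = False
    for scc in nx.strongly_connected_components(simple):
        if scc & b.focal_fiber and scc & b.regulators:
            has_cycle = True
            cycle_nodes |= scc
    pool = cycle_nodes if has_cycle else b.members
    has_self_loop = any(b.subgraph.has_self_loop(n) for n in pool)
    return has_cycle, has_self_loop


def _per_fiber_label(b: BuildingBlock, fiber: frozenset[str]) -> str:
    """|n,l> label of one fiber measured inside the block subgraph."""
    sub = b.subgraph
    regs = {u for v in fiber for u in sub.predecessors(v)} - set(fiber)
    br = branching_ratio(sub, min(fiber))
    n = 0 if br.status == STATUS_FINITE else int(round(br.value))
    return f"|{n},{len(regs)}>"


def classify_block(
    b: BuildingBlock, p: FiberPartition, integer_tol: float = 1e-6
) -> BlockClass:
    """Assign a building block to its taxonomic family.

    Single-fiber blocks are Fibonacci when both structural conditions hold
    (fiber-regulator cycle + self-loop on it), else |n,l> with n = round(r)
    (n = 0 for finite trees) and l = number of regulators.  Multi-fiber
    blocks are composite feedback Fibonaccis when a cycle crosses two or
    more fibers, composite feedforward Fibonaccis when the composition is
    acyclic but the inherited ratio is noninteger, and multilayer
    compositions of |n,l> blocks otherwise.
    """
    r = b.branching.value
    contained = _contained_nontrivial_fibers(b, p)
    nf = len(contained)
    is_integer = abs(r - round(r)) <= integer_tol
    if nf <= 1:
        cond_cycle, cond_self_loop = fibonacci_conditions(b)
        if cond_cycle and cond_self_loop:
            return BlockClass(
                FAMILY_FIBONACCI, None, None, r, max(nf, 1),
                f"Fibonacci (r={r:.3f})",
            )
        n = 0 if b.branching.status == STATUS_FINITE else int(round(r))
        l = len(b.regulators)
        return BlockClass(FAMILY_NL, n, l, r, max(nf, 1), f"|{n},{l}>")
    if _has_interfiber_cycle(b, contained):
        return BlockClass(
            FAMILY_COMPOSITE_FB, None, None, r, nf,
            f"Composite Feedback Fibonacci (r={r:.3f})",
        )
    if not is_integer:
        return BlockClass(
            FAMILY_COMPOSITE_FF, None, None, r, nf,
            f"Composite Feedforward Fibonacci (r={r:.3f})",
        )
    ordered = [b.focal_fiber] + sorted(
        (f for f in contained if f != b.focal_fiber), key=min
    )
    label = "(+)".join(_per_fiber_label(b, f) for f in ordered)
    return BlockClass(FAMILY_MULTILAYER, None, None, r, nf, label)


def assign_defining_blocks(
    blocks: list[BuildingBlock],
) -> dict[frozenset[str], BuildingBlock]:
    """Map every focal fiber to its defining block.

    A fiber contained in several blocks is defined by the member-count
    smallest one (shortest cycles dominate its dynamics); ties break by the
    block's lexicographically minimal member.  Larger blocks remain as
    higher-order corrections.
    """
    out: dict[frozenset[str], BuildingBlock] = {}
    for blk in blocks:
        fiber = blk.focal_fiber
        candidates = [c for c in blocks if fiber <= c.members]
        candidates.sort(key=lambda c: (len(c.members), min(c.members)))
        out[fiber] = candidates[0]
    return out


def block_report(
    blocks: list[BuildingBlock],
    classes: list[BlockClass],
    defining: dict[frozenset[str], BuildingBlock],
) -> str:
    """JSON report: per block — members, regulators, r, family, defining flag."""
    rows = []
    for blk, cls in zip(blocks, classes):
        rows.append(
            {
                "fiber": sorted(blk.focal_fiber),
                "regulators": sorted(blk.regulators),
                "members": sorted(blk.members),
                "r": round(blk.branching.value, 6),
                "status": blk.branching.status,
                "family": cls.family,
                "label": cls.label,
                "n_fibers_involved": cls.n_fibers_involved,
                "defining": defining.get(blk.focal_fiber) is blk,
            }
        )
    return json.dumps(rows, indent=2)
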