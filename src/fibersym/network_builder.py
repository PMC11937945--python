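"""Enzyme-network construction from reaction tables, and synthetic fixtures.

An enzyme–enzyme network connects enzyme e1 to enzyme e2 through metabolite
m whenever m is a product of a reaction catalyzed by e1 and a substrate of a
reaction catalyzed by e2.  Each linking metabolite contributes a distinct
typed edge, preserving the multi-edge structure through which enzyme pairs
communicate via several metabolites.  Ubiquitous ("currency") metabolites
such as ATP or H2O are removed via an explicit, user-supplied exclusion
list; :func:`rank_metabolites` supports choosing that list.

The module also houses the package's synthetic generators: lifted cycle
blocks realizing arbitrary linear layer-count recurrences, planted-fiber
random networks with known ground truth, and the canonical 4-node toy.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .graph_core import DirectedMultigraph, GraphFormatError

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Reaction:
    reaction_id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    enzymes: tuple[str, ...]

    def __post_init__(self):
        if not self.substrates or not self.products:
            raise GraphFormatError(
                f"reaction {self.reaction_id!r}: substrates and products must be non-empty"
            )
        for name, vals in (("substrates", self.substrates),
                           ("products", self.products),
                           ("enzymes", self.enzymes)):
            if len(set(vals)) != len(vals):
                raise GraphFormatError(
                    f"reaction {self.reaction_id!r}: duplicate entries in {name}"
                )


@dataclass
class ReactionTable:
    """A list of reactions: id, substrate/product metabolites, catalyzing enzymes."""

    reactions: list[Reaction] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.reactions)

    def __iter__(self):
        return iter(self.reactions)

    @classmethod
    def from_records(cls, records) -> "ReactionTable":
        """Build from iterables of (reaction_id, substrates, products, enzymes)."""
        rxns = [
            Reaction(str(rid), tuple(map(str, s)), tuple(map(str, p)), tuple(map(str, e)))
            for rid, s, p, e in records
        ]
        return cls(rxns)

    @classmethod
    def read_table(cls, path, sep: str | None = None) -> "ReactionTable":
        """Read a TSV/CSV with columns reaction_id, substrates, products, enzymes.

        List-valued columns are semicolon-separated.
        """
        if sep is None:
            sep = "\t" if str(path).endswith(".tsv") else None
        try:
            df = pd.read_csv(path, sep=sep, comment="#", dtype=str, engine="python")
        except pd.errors.EmptyDataError:
            raise GraphFormatError(f"empty reaction table: {path}") from None
        required = {"reaction_id", "substrates", "products", "enzymes"}
        if not required <= set(df.columns):
            raise GraphFormatError(
                f"reaction table {path} missing columns {sorted(required - set(df.columns))}"
            )

        def split(cell) -> tuple[str, ...]:
            if pd.isna(cell) or not str(cell).strip():
                return ()
            return tuple(x.strip() for x in str(cell).split(";") if x.strip())

        return cls.from_records(
            (row["reaction_id"], split(row["substrates"]), split(row["products"]),
             split(row["enzymes"]))
            for _, row in df.iterrows()
        )

    @classmethod
    def read_json(cls, path) -> "ReactionTable":
        """Read a JSON list of objects with the same four fields."""
        with open(path) as fh:
            data = json.load(fh)
        return cls.from_records(
            (r["reaction_id"], r["substrates"], r["products"], r.get("enzymes", []))
            for r in data
        )


def build_enzyme_network(
    rt: ReactionTable,
    excluded_metabolites: set[str] | frozenset[str] = frozenset(),
    add_reverse: bool = False,
) -> DirectedMultigraph:
    """Construct the enzyme–enzyme directed multigraph from a reaction table.

    For every non-excluded metabolite m that is a product of reaction R1
    (enzyme e1) and a substrate of reaction R2 (enzyme e2), an edge e1->e2
    with edge_type m is added; repeated reaction pairs raise the edge's
    multiplicity.  Self-loops arise when e1 == e2.  Reactions are taken as
    written; ``add_reverse=True`` additionally treats every reaction as
    reversible (substrates and products swapped).

    Reactions with no enzymes contribute no edges (logged).  An empty table
    yields the empty graph.
    """
    excluded = set(excluded_metabolites)
    reactions = []
    for r in rt:
        if not r.enzymes:
            logger.warning("reaction %s has no enzymes; skipped", r.reaction_id)
            continue
        reactions.append(r)
        if add_reverse:
            reactions.append(
                Reaction(r.reaction_id + "__rev", r.products, r.substrates, r.enzymes)
            )

    # metabolite -> producing / consuming enzymes
    producers: dict[str, list[str]] = {}
    consumers: dict[str, list[str]] = {}
    for r in reactions:
        for m in r.products:
            if m not in excluded:
                producers.setdefault(m, []).extend(r.enzymes)
        for m in r.substrates:
            if m not in excluded:
                consumers.setdefault(m, []).extend(r.enzymes)

    g = DirectedMultigraph()
    linking = sorted(set(producers) & set(consumers))
    contributing: set[str] = set()
    for m in linking:
        for e1 in producers[m]:
            for e2 in consumers[m]:
                g.add_edge(e1, e2, edge_type=m)
                contributing.add(e1)
                contributing.add(e2)
    for e in contributing:
        g.add_node(e)
    return g


def rank_metabolites(rt: ReactionTable) -> pd.Series:
    """Occurrence count per metabolite, sorted descending (ties lexicographic).

    A metabolite's occurrence is the number of reactions in which it appears
    as substrate or product; supports the manual discard of ubiquitous
    metabolites.
    """
    counts: dict[str, int] = {}
    for r in rt:
        for m in set(r.substrates) | set(r.products):
            counts[m] = counts.get(m, 0) + 1
    items = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.Series(
        [c for _, c in items],
        index=pd.Index([m for m, _ in items], name="metabolite"),
        name="occurrence",
        dtype=int,
    )


# -- synthetic fixtures ------------------------------------------------------


def make_recurrence_block(
    cycle_terms: list[tuple[int, int]],
) -> tuple[DirectedMultigraph, str]:
    """Build a block whose root layer sequence obeys ``a_i = sum n_d * a_{i-d}``.

    Each term ``(d, n)`` contributes a directed cycle of length d through the
    root with total path multiplicity n: d=1 becomes a self-loop of
    multiplicity n; d>=2 becomes a chain of d-1 fresh nodes back to the root
    with one chain edge carrying multiplicity n.  Terms with equal d merge by
    summing n.  Returns (graph, root node id).
    """
    if not cycle_terms:
        raise ValueError("at least one (length, coefficient) term required")
    merged: dict[int, int] = {}
    for d, n in cycle_terms:
        if d < 1 or n < 1:
            raise ValueError(f"cycle length and coefficient must be >= 1, got ({d}, {n})")
        merged[d] = merged.get(d, 0) + n
    root = "F"
    g = DirectedMultigraph()
    g.add_node(root)
    for d in sorted(merged):
        n = merged[d]
        if d == 1:
            g.add_edge(root, root, multiplicity=n)
            continue
        chain = [f"c{d}_{k}" for k in range(1, d)]
        path = [root, *chain, root]
        for i, (u, v) in enumerate(zip(path[:-1], path[1:])):
            g.add_edge(u, v, multiplicity=n if i == 0 else 1)
    return g, root


def make_two_fiber_toy() -> tuple[DirectedMultigraph, list[frozenset[str]]]:
    """The canonical 4-node toy with two self-loop-driven fibers {A,B} and {C,D}.

    A carries a self-loop and feeds B; C carries a self-loop and feeds D.
    The two components use distinct metabolite types so the two fibers stay
    separate under balanced coloring.  Returns (graph, expected partition).
    """
    g = DirectedMultigraph.from_edges(
        [
            ("A", "A", "m1"),
            ("A", "B", "m1"),
            ("C", "C", "m2"),
            ("C", "D", "m2"),
        ]
    )
    return g, [frozenset({"A", "B"}), frozenset({"C", "D"})]


def make_complexity_ladder() -> list[tuple[DirectedMultigraph, str]]:
    """The five-step edge-addition ladder from a chain fiber to a feedback composite.

    Fibers are lifted to two members each so that composition is visible to
    balanced coloring; the downstream fiber is regulated through a distinct
    metabolite type, keeping it separate from the single-node regulator.
    Steps (each extends the previous graph; a base-edge addition lifts to one
    edge per target-fiber member):

    1. auto-regulated fiber (|1,0>);
    2. + external regulator (|1,1>);
    3. + feedback edge fiber->regulator (simple Fibonacci, r = 1.618);
    4. + feed-forward regulation of a second fiber (composite feedforward
       Fibonacci, r unchanged);
    5. + feedback edges from the second fiber (composite feedback Fibonacci,
       r = 2).

    Returns a list of (graph, focal fiber member) pairs.
    """
    steps: list[tuple[DirectedMultigraph, str]] = []
    edges: list[tuple[str, str, str]] = [("F1", "F1", "m1"), ("F1", "F2", "m1")]
    steps.append((DirectedMultigraph.from_edges(edges), "F1"))
    edges = edges + [("R", "F1", "m1"), ("R", "F2", "m1")]
    steps.append((DirectedMultigraph.from_edges(edges), "F1"))
    edges = edges + [("F1", "R", "m1")]
    steps.append((DirectedMultigraph.from_edges(edges), "F1"))
    edges = edges + [("F1", "G1", "m2"), ("F1", "G2", "m2")]
    steps.append((DirectedMultigraph.from_edges(edges), "G1"))
    edges = edges + [("G1", "F1", "m1"), ("G1", "F2", "m1")]
    steps.append((DirectedMultigraph.from_edges(edges), "F1"))
    return steps


def make_planted_fiber_network(
    n_fibers: int,
    fiber_sizes: list[int],
    n_regulators: int,
    seed: int,
) -> tuple[DirectedMultigraph, list[frozenset[str]]]:
    """Random network with planted fibers and exactly known ground truth.

    Every member of a planted fiber receives the identical in-neighborhood
    (same regulator sources, types and multiplicities), which guarantees
    isomorphic input trees.  Regulators carry pairwise-distinct self-loop
    multiplicities (>= 4) while fiber in-edges use multiplicities <= 3, and
    fiber in-neighborhood signatures are deduplicated, so the ground-truth
    partition (each fiber one group, each regulator a singleton) is exactly
    the minimal balanced coloring.

    Returns (graph, ground-truth partition ordered by decreasing size then
    lexicographic minimum member).
    """
    if n_fibers < 1 or n_regulators < 1:
        raise ValueError("need at least one fiber and one regulator")
    if len(fiber_sizes) != n_fibers:
        raise ValueError("fiber_sizes must have length n_fibers")
    if any(s < 1 for s in fiber_sizes):
        raise ValueError("fiber sizes must be >= 1")
    rng = np.random.default_rng(seed)
    g = DirectedMultigraph()
    regulators = [f"R{k:02d}" for k in range(n_regulators)]
    for k, r in enumerate(regulators):
        g.add_edge(r, r, multiplicity=k + 4)  # distinct >= 4: keeps regulators singleton

    seen_signatures: set[tuple] = set()
    partition: list[frozenset[str]] = []
    for i in range(n_fibers):
        members = [f"F{i:02d}_{j:02d}" for j in range(fiber_sizes[i])]
        attempt = 0
        while True:
            attempt += 1
            hi = 3 + attempt // 10  # widen the range if the signature space is tight
            k = int(rng.integers(1, n_regulators + 1))
            srcs = sorted(rng.choice(n_regulators, size=k, replace=False).tolist())
            mults = [int(rng.integers(1, hi + 1)) for _ in srcs]
            signature = tuple(zip(srcs, mults))
            if len(srcs) == 1 and mults[0] == srcs[0] + 4:
                continue  # would replicate regulator srcs[0]'s own in-profile
            if signature not in seen_signatures:
                seen_signatures.add(signature)
                break
        for member in members:
            for s, m in signature:
                g.add_edge(regulators[s], member, multiplicity=m)
        partition.append(frozenset(members))
    partition.extend(frozenset({r}) for r in regulators)
    partition.sort(key=lambda f: (-len(f), min(f)))
    return g, partition
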