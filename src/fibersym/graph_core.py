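"""Directed multigraph container, standard-format I/O, and structural decomposition.

The universal substrate of the package is a directed multigraph whose edges
carry a type label (in enzyme networks: the metabolite through which two
enzymes communicate) and an integer multiplicity.  Parallel edges with the
same (source, target, type) are always stored merged, with multiplicities
summed, so two graphs built from differently-split edge records compare
equal.  All node/edge orderings exposed by this module are lexicographic,
so every downstream output is byte-for-byte reproducible.
"""

from __future__ import annotations

import io
from collections import Counter
from typing import Iterable, Iterator, Mapping

import networkx as nx
import pandas as pd

DEFAULT_EDGE_TYPE = "metabolic"

#: edge-type label used when parallel typed edges are collapsed
COLLAPSED_EDGE_TYPE = "any"


class GraphFormatError(ValueError):
    """Raised for malformed edge-list / reaction-table input."""


class DirectedMultigraph:
    """A directed multigraph with typed, multiplicity-weighted edges.

    Edges are keyed by ``(source, target, edge_type)``; adding an edge that
    already exists sums the multiplicities (canonical merged form).
    Self-loops are permitted.
    """

    __slots__ = ("_nodes", "_edges", "_in", "_out")

    def __init__(self) -> None:
        self._nodes: set[str] = set()
        self._edges: dict[tuple[str, str, str], int] = {}
        self._in: dict[str, dict[tuple[str, str], int]] = {}
        self._out: dict[str, dict[tuple[str, str], int]] = {}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_edges(
        cls,
        edges: Iterable[tuple],
        nodes: Iterable[str] = (),
    ) -> "DirectedMultigraph":
        """Build a graph from ``(source, target[, edge_type[, multiplicity]])`` tuples."""
        g = cls()
        for n in nodes:
            g.add_node(n)
        for e in edges:
            g.add_edge(*e)
        return g

    def add_node(self, node: str) -> None:
        node = str(node)
        self._nodes.add(node)
        self._in.setdefault(node, {})
        self._out.setdefault(node, {})

    def add_edge(
        self,
        source: str,
        target: str,
        edge_type: str = DEFAULT_EDGE_TYPE,
        multiplicity: int = 1,
    ) -> None:
        if multiplicity < 1 or int(multiplicity) != multiplicity:
            raise GraphFormatError(
                f"multiplicity must be a positive integer, got {multiplicity!r} "
                f"on edge {source!r}->{target!r}"
            )
        source, target, edge_type = str(source), str(target), str(edge_type)
        multiplicity = int(multiplicity)
        self.add_node(source)
        self.add_node(target)
        key = (source, target, edge_type)
        self._edges[key] = self._edges.get(key, 0) + multiplicity
        ik = (source, edge_type)
        self._in[target][ik] = self._in[target].get(ik, 0) + multiplicity
        ok = (target, edge_type)
        self._out[source][ok] = self._out[source].get(ok, 0) + multiplicity

    # -- inspection -------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        """Node identifiers in lexicographic order."""
        return sorted(self._nodes)

    def __contains__(self, node: str) -> bool:
        return node in self._nodes

    def number_of_nodes(self) -> int:
        return len(self._nodes)

    def number_of_edge_records(self) -> int:
        """Distinct (source, target, type) records."""
        return len(self._edges)

    def total_multiplicity(self) -> int:
        """Total number of directed edges, counting multiplicity."""
        return sum(self._edges.values())

    def edges(self) -> Iterator[tuple[str, str, str, int]]:
        """Yield ``(source, target, edge_type, multiplicity)`` sorted lexicographically."""
        for key in sorted(self._edges):
            yield (*key, self._edges[key])

    def multiplicity(self, source: str, target: str, edge_type: str = DEFAULT_EDGE_TYPE) -> int:
        return self._edges.get((source, target, edge_type), 0)

    def in_edges(self, node: str) -> list[tuple[str, str, int]]:
        """Incoming ``(source, edge_type, multiplicity)`` of *node*, sorted."""
        return [(u, t, m) for (u, t), m in sorted(self._in.get(node, {}).items())]

    def out_edges(self, node: str) -> list[tuple[str, str, int]]:
        """Outgoing ``(target, edge_type, multiplicity)`` of *node*, sorted."""
        return [(v, t, m) for (v, t), m in sorted(self._out.get(node, {}).items())]

    def predecessors(self, node: str) -> set[str]:
        return {u for (u, _t) in self._in.get(node, {})}

    def successors(self, node: str) -> set[str]:
        return {v for (v, _t) in self._out.get(node, {})}

    def has_self_loop(self, node: str) -> bool:
        return any(u == node for (u, _t) in self._in.get(node, {}))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DirectedMultigraph):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __hash__(self) -> int:  # pragma: no cover - identity-free value type
        return hash((frozenset(self._nodes), frozenset(self._edges.items())))

    def __repr__(self) -> str:
        return (
            f"DirectedMultigraph({self.number_of_nodes()} nodes, "
            f"{self.number_of_edge_records()} edge records, "
            f"total multiplicity {self.total_multiplicity()})"
        )

    # -- transforms -------------------------------------------------------

    def copy(self) -> "DirectedMultigraph":
        g = DirectedMultigraph()
        for n in self._nodes:
            g.add_node(n)
        for (u, v, t), m in self._edges.items():
            g.add_edge(u, v, t, m)
        return g

    def canonicalize(self) -> "DirectedMultigraph":
        """Return the canonical merged form (idempotent; storage is already merged)."""
        return self.copy()

    def collapse_parallel(self) -> "DirectedMultigraph":
        """Merge typed parallel edges between each node pair into one edge.

        Multiplicities are summed and the edge type is replaced by the
        sentinel :data:`COLLAPSED_EDGE_TYPE`; used when metabolite identity
        on links is treated as irrelevant.
        """
        g = DirectedMultigraph()
        for n in self._nodes:
            g.add_node(n)
        for (u, v, _t), m in self._edges.items():
            g.add_edge(u, v, COLLAPSED_EDGE_TYPE, m)
        return g

    def subgraph(self, nodes: Iterable[str]) -> "DirectedMultigraph":
        """Induced subgraph: keeps every edge whose endpoints are both in *nodes*."""
        keep = set(nodes)
        missing = keep - self._nodes
        if missing:
            raise KeyError(f"nodes not in graph: {sorted(missing)}")
        g = DirectedMultigraph()
        for n in keep:
            g.add_node(n)
        for (u, v, t), m in self._edges.items():
            if u in keep and v in keep:
                g.add_edge(u, v, t, m)
        return g

    def to_networkx(self) -> nx.MultiDiGraph:
        g = nx.MultiDiGraph()
        g.add_nodes_from(self.nodes)
        for u, v, t, m in self.edges():
            g.add_edge(u, v, edge_type=t, multiplicity=m)
        return g

    def to_simple_digraph(self, weighted: bool = False) -> nx.DiGraph:
        """Simple-digraph view: one arc per connected ordered pair.

        With ``weighted=True`` each arc carries the total multiplicity over
        all parallel typed edges as attribute ``weight``.
        """
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for (u, v, _t), m in self._edges.items():
            if g.has_edge(u, v):
                g[u][v]["weight"] += m
            else:
                g.add_edge(u, v, weight=m)
        if not weighted:
            for _u, _v, d in g.edges(data=True):
                d["weight"] = 1
        return g


# -- I/O -------------------------------------------------------------------

_STANDARD_COLUMNS = ("source", "target", "edge_type", "multiplicity")


def read_edge_list(
    path, dialect: Mapping[str, str] | None = None, sep: str | None = None
) -> DirectedMultigraph:
    """Read an edge-list TSV/CSV into a canonical :class:`DirectedMultigraph`.

    Parameters
    ----------
    path:
        File path (or buffer).  ``#`` comment lines are ignored.
    dialect:
        Optional mapping from standard column names (``source``, ``target``,
        ``edge_type``, ``multiplicity``) to the file's actual column names.
    sep:
        Column separator; inferred when omitted (tab for ``.tsv``, else sniffed).
    """
    dialect = dict(dialect or {})
    colmap = {std: dialect.get(std, std) for std in _STANDARD_COLUMNS}
    if sep is None:
        name = str(getattr(path, "name", path))
        sep = "\t" if name.endswith(".tsv") else None
    try:
        df = pd.read_csv(
            path, sep=sep, comment="#", dtype=str, engine="python", skip_blank_lines=True
        )
    except pd.errors.EmptyDataError:
        raise GraphFormatError(f"empty edge-list file: {path}") from None
    for std in ("source", "target"):
        if colmap[std] not in df.columns:
            raise GraphFormatError(
                f"missing required column {colmap[std]!r} in {path} "
                f"(found: {list(df.columns)})"
            )
    g = DirectedMultigraph()
    has_type = colmap["edge_type"] in df.columns
    has_mult = colmap["multiplicity"] in df.columns
    for idx, row in df.iterrows():
        src, tgt = row[colmap["source"]], row[colmap["target"]]
        if pd.isna(src) or pd.isna(tgt):
            raise GraphFormatError(f"row {idx}: missing source/target")
        etype = row[colmap["edge_type"]] if has_type and pd.notna(row[colmap["edge_type"]]) else DEFAULT_EDGE_TYPE
        mult = 1
        if has_mult and pd.notna(row[colmap["multiplicity"]]):
            try:
                mult = int(row[colmap["multiplicity"]])
            except ValueError:
                raise GraphFormatError(
                    f"row {idx}: non-integer multiplicity {row[colmap['multiplicity']]!r}"
                ) from None
        if mult < 1:
            raise GraphFormatError(f"row {idx}: non-positive multiplicity {mult}")
        g.add_edge(str(src), str(tgt), str(etype), mult)
    return g


def write_graph(g: DirectedMultigraph, path, format: str = "edge_list_tsv") -> None:
    """Write *g* to *path* as ``edge_list_tsv``, ``graphml`` or ``dot``.

    The TSV form round-trips exactly through :func:`read_edge_list`.
    Multiplicity is stored as an edge attribute named ``multiplicity``.
    """
    if format == "edge_list_tsv":
        rows = list(g.edges())
        df = pd.DataFrame(rows, columns=list(_STANDARD_COLUMNS))
        df.to_csv(path, sep="\t", index=False)
    elif format == "graphml":
        nx.write_graphml(g.to_networkx(), path)
    elif format == "dot":
        _write_dot(g, path)
    else:
        raise ValueError(f"unknown graph format: {format!r}")


def _write_dot(g: DirectedMultigraph, path) -> None:
    buf = io.StringIO()
    buf.write("digraph G {\n")
    for n in g.nodes:
        buf.write(f'  "{n}";\n')
    for u, v, t, m in g.edges():
        buf.write(f'  "{u}" -> "{v}" [label="{t}", multiplicity={m}];\n')
    buf.write("}\n")
    if hasattr(path, "write"):
        path.write(buf.getvalue())
    else:
        with open(path, "w") as fh:
            fh.write(buf.getvalue())


# -- structural decomposition ----------------------------------------------


def strongly_connected_components(g: DirectedMultigraph) -> list[set[str]]:
    """Maximal SCCs, ordered by decreasing size then lexicographic minimum member."""
    sccs = [set(c) for c in nx.strongly_connected_components(g.to_simple_digraph())]
    sccs.sort(key=lambda c: (-len(c), min(c)))
    return sccs


#: node roles used in the structural breakdown of enzyme networks
ROLE_SCC = "scc_member"
ROLE_CONNECTOR = "connector"
ROLE_KOUT_SHELL = "kout_shell"


def classify_node_roles(g: DirectedMultigraph) -> pd.DataFrame:
    """Partition nodes into SCC members, connectors and the k_out shell.

    A node is an SCC member if it lies in an SCC of size >= 2 or carries a
    self-loop (a cycle of length 1).  A connector is a non-SCC node sending
    at least one edge into an SCC.  Every remaining node belongs to the
    k_out shell, which only receives information from SCCs or other shell
    nodes (isolated nodes default here too).

    Returns a DataFrame indexed by node with columns ``role`` and ``scc_id``
    (the index of the node's SCC in the ordered SCC list, or pandas NA).
    """
    sccs = strongly_connected_components(g)
    scc_of: dict[str, int] = {}
    members: set[str] = set()
    for i, c in enumerate(sccs):
        for n in c:
            scc_of[n] = i
        if len(c) >= 2:
            members |= c
        else:
            (n,) = c
            if g.has_self_loop(n):
                members.add(n)
    roles = {}
    for n in g.nodes:
        if n in members:
            roles[n] = ROLE_SCC
        elif any(v in members for v in g.successors(n)):
            roles[n] = ROLE_CONNECTOR
        else:
            roles[n] = ROLE_KOUT_SHELL
    df = pd.DataFrame(
        {
            "role": [roles[n] for n in g.nodes],
            "scc_id": pd.array(
                [scc_of[n] if n in members else None for n in g.nodes], dtype="Int64"
            ),
        },
        index=pd.Index(g.nodes, name="node"),
    )
    return df
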