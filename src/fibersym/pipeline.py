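"""End-to-end analysis pipeline: configuration, orchestration, report.

Runs the full workflow on an input graph (or reaction table): structural
decomposition, minimal balanced coloring, base construction, building-block
extraction and classification, and optional comparator benchmarks.  All
randomness is seeded and every output embeds a provenance hash of the
configuration, so identical configs produce byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .building_blocks import (
    BlockClass,
    BuildingBlock,
    assign_defining_blocks,
    block_report,
    classify_block,
    extract_block,
)
from .comparators import MotifCensus, adjusted_rand_index, louvain_partition, motif_zscores
from .fibration import FiberPartition, build_base, find_fibers, read_partition, write_partition
from .graph_core import (
    DirectedMultigraph,
    classify_node_roles,
    read_edge_list,
    strongly_connected_components,
    write_graph,
)
from .network_builder import ReactionTable, build_enzyme_network

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """All knobs of a full analysis run; every field has a documented default."""

    graph_path: str | None = None
    reaction_table_path: str | None = None
    excluded_metabolites: list[str] = field(default_factory=list)
    collapse_parallel: bool = False
    branching_tol: float = 1e-9
    branching_max_iter: int = 10_000
    integer_tol: float = 1e-6
    run_motifs: bool = False
    motif_n_random: int = 1000
    motif_n_swaps: int | None = None
    run_modules: bool = False
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if self.branching_tol <= 0 or self.integer_tol <= 0:
            raise ValueError("tolerances must be > 0")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)


def version_and_provenance(config: AnalysisConfig) -> str:
    """Tool version plus a hash of the canonicalized config (seeds included).

    The output directory is excluded: it determines where results land, not
    what they are.
    """
    fields = {k: v for k, v in asdict(config).items() if k != "output_dir"}
    canonical = json.dumps(fields, sort_keys=True)
    digest = hashlib.sha256(canonical.encode()).hexdigest()[:16]
    return f"fibersym {__version__} | config sha256:{digest} | seed {config.seed}"


@dataclass
class AnalysisReport:
    """Aggregated results of a full run."""

    provenance: str
    n_nodes: int
    n_edge_records: int
    total_multiplicity: int
    scc_sizes: list[int]
    role_counts: dict[str, int]
    partition: FiberPartition
    n_fibers_total: int
    n_fibers_nontrivial: int
    blocks: list[BuildingBlock]
    classes: list[BlockClass]
    defining: dict
    base_nodes: int
    modules_q: float | None = None
    modules_ari_vs_fibers: float | None = None
    motif_census: MotifCensus | None = None

    def summary_text(self) -> str:
        lines = [
            f"# {self.provenance}",
            f"nodes: {self.n_nodes}",
            f"edge records: {self.n_edge_records} (total multiplicity {self.total_multiplicity})",
            f"SCC sizes: {self.scc_sizes}",
            "roles: " + ", ".join(f"{k}={v}" for k, v in sorted(self.role_counts.items())),
            f"fibers: {self.n_fibers_total} total, {self.n_fibers_nontrivial} nontrivial",
            f"base nodes: {self.base_nodes}",
        ]
        for blk, cls in zip(self.blocks, self.classes):
            defin = "defining" if self.defining.get(blk.focal_fiber) is blk else "higher-order"
            lines.append(
                f"block fiber={sorted(blk.focal_fiber)} family={cls.family} "
                f"label={cls.label} r={blk.branching.value:.3f} ({defin})"
            )
        if self.modules_q is not None:
            lines.append(f"modules: Q={self.modules_q:.4f} ARI(fibers, modules)={self.modules_ari_vs_fibers:.4f}")
        if self.motif_census is not None:
            for row in self.motif_census.to_rows():
                lines.append(
                    f"motif {row['motif']}: N={row['observed']} <N>={row['null_mean']:.2f} "
                    f"sd={row['null_sd']:.2f} Z={row['z']:.2f} significant={row['significant']}"
                )
        return "\n".join(lines) + "\n"


def load_graph(config: AnalysisConfig) -> DirectedMultigraph:
    if config.graph_path:
        return read_edge_list(config.graph_path)
    if config.reaction_table_path:
        rt = ReactionTable.read_table(config.reaction_table_path)
        return build_enzyme_network(rt, set(config.excluded_metabolites))
    raise ValueError("config must provide graph_path or reaction_table_path")


def run_full_analysis(
    config: AnalysisConfig, graph: DirectedMultigraph | None = None
) -> AnalysisReport:
    """Run the complete pipeline and (optionally) write all artifacts.

    Errors from individual stages propagate with stage context.  When
    ``config.output_dir`` is set, writes partition TSV, base-graph TSV,
    block JSON, optional census TSV, and the human-readable summary.
    """
    provenance = version_and_provenance(config)
    g = graph if graph is not None else load_graph(config)

    def stage(name, fn, *args, **kwargs):
        logger.info("stage %s", name)
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage {name!r} failed: {exc}") from exc

    sccs = stage("scc", strongly_connected_components, g)
    roles = stage("roles", classify_node_roles, g)
    partition = stage("fibers", find_fibers, g, collapse_parallel=config.collapse_parallel)
    base = stage("base", build_base, g, partition)
    blocks = [
        stage("blocks", extract_block, g, partition, i,
              tol=config.branching_tol, max_iter=config.branching_max_iter)
        for i in range(len(partition.fibers))
        if len(partition.fibers[i]) >= 2
    ]
    classes = [stage("classify", classify_block, b, partition, config.integer_tol) for b in blocks]
    defining = stage("defining", assign_defining_blocks, blocks)

    modules_q = ari = None
    if config.run_modules:
        mp = stage("modules", louvain_partition, g, seed=config.seed)
        modules_q = mp.q
        fiber_labels = partition.class_index()
        ari = adjusted_rand_index(fiber_labels, mp.labels)
    census = None
    if config.run_motifs:
        census = stage(
            "motifs", motif_zscores, g,
            n_random=config.motif_n_random, n_swaps=config.motif_n_swaps, seed=config.seed,
        )

    report = AnalysisReport(
        provenance=provenance,
        n_nodes=g.number_of_nodes(),
        n_edge_records=g.number_of_edge_records(),
        total_multiplicity=g.total_multiplicity(),
        scc_sizes=[len(c) for c in sccs],
        role_counts=roles["role"].value_counts().to_dict(),
        partition=partition,
        n_fibers_total=len(partition.fibers),
        n_fibers_nontrivial=len(partition.nontrivial_fibers()),
        blocks=blocks,
        classes=classes,
        defining=defining,
        base_nodes=base.graph.number_of_nodes(),
        modules_q=modules_q,
        modules_ari_vs_fibers=ari,
        motif_census=census,
    )

    if config.output_dir:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = f"# {provenance}\n"
        with open(out / "fibers.tsv", "w") as fh:
            fh.write(header)
            write_partition(partition, fh)
        with open(out / "base.tsv", "w") as fh:
            fh.write(header)
            write_graph(base.graph, fh)
        (out / "blocks.json").write_text(block_report(blocks, classes, defining))
        (out / "summary.txt").write_text(report.summary_text())
        if census is not None:
            rows = census.to_rows()
            with open(out / "motifs.tsv", "w") as fh:
                fh.write(header)
                fh.write("motif\tobserved\tnull_mean\tnull_sd\tz\tsignificant\n")
                for row in rows:
                    fh.write(
                        f"{row['motif']}\t{row['observed']}\t{row['null_mean']}\t"
                        f"{row['null_sd']}\t{row['z']}\t{row['significant']}\n"
                    )
    return report


def configure_logging(verbose: bool = False) -> None:
    """Stage logs to stderr; results never interleave with logs."""
    logging.basicConfig(
        stream=sys.stderr,
        level=logging.INFO if verbose else logging.WARNING,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )
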