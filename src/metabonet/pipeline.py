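"""End-to-end orchestration: parse -> build -> filter -> annotate -> export.

The stage order is fixed: build the merged network, compute seed
distances once, apply the distance filter, join all three annotation
layers, apply the expression filter, prune structurally, export.
Annotation precedes expression filtering so the removed-gene lists in the
run report carry their annotations.  Distances reported in exports are
the pre-prune values; later filters never trigger recomputation.

Every run writes four export files (node table, edge table, SIF,
GraphML) plus a deterministic JSON run report recording node/edge counts
after every stage, join statistics, and per-filter removal lists with
reasons.  Any stage failure aborts with the stage name and removes
partial outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import export as export_mod
from .annotate import (
    AnnotationTables,
    JoinReport,
    annotate_biofluid,
    annotate_expression,
    annotate_prognosis,
    load_annotation_tables,
)
from .filters import (
    DistanceMap,
    FilterConfig,
    compute_seed_distances,
    filter_by_distance,
    filter_unexpressed,
    prune_structure,
)
from .kgml import read_kgml
from .network import MetaboNetwork, build_network, network_summary

logger = logging.getLogger(__name__)

STAGES = (
    "build",
    "distance_filter",
    "annotate",
    "expression_filter",
    "prune",
)

OUTPUT_FILES = ("node_table.tsv", "edge_table.tsv", "network.sif", "network.graphml")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass(frozen=True)
class RunConfig:
    """Everything one pipeline run needs."""

    pathway_paths: tuple[str, ...]
    seed_ids: tuple[str, ...]
    expression_path: str
    prognosis_path: str
    biofluid_path: str
    out_dir: str
    tissue: str = "hepatocytes"
    filters: FilterConfig = field(default_factory=FilterConfig)


@dataclass
class RunReport:
    """Per-stage accounting for one pipeline run."""

    stages: list[dict] = field(default_factory=list)
    joins: dict = field(default_factory=dict)
    removed: dict = field(default_factory=dict)
    outputs: list[str] = field(default_factory=list)

    def record_stage(self, name: str, network: MetaboNetwork) -> None:
        s = network_summary(network)
        self.stages.append(
            {
                "stage": name,
                "n_nodes": s.n_nodes,
                "n_metabolites": s.n_metabolites,
                "n_metabolic_genes": s.n_metabolic_genes,
                "n_signaling_genes": s.n_signaling_genes,
                "n_edges": s.n_edges,
            }
        )

    def record_removed(
        self, stage: str, before: MetaboNetwork, after: MetaboNetwork, reason: str
    ) -> None:
        gone = sorted(set(before.graph.nodes) - set(after.graph.nodes))
        self.removed[stage] = [
            {
                "node_id": n,
                "reason": reason,
                "attributes": {
                    k: v for k, v in before.graph.nodes[n].items() if k != "kind"
                },
            }
            for n in gone
        ]

    def record_join(self, layer: str, report: JoinReport) -> None:
        self.joins[layer] = {
            "matched": report.matched,
            "unmatched_ids": list(report.unmatched_ids),
        }

    def to_json(self) -> str:
        return json.dumps(
            {
                "stages": self.stages,
                "joins": self.joins,
                "removed": self.removed,
                "outputs": self.outputs,
            },
            indent=2,
            sort_keys=True,
        )


def run_pipeline_from_objects(
    pathways,
    tables: AnnotationTables,
    seed_ids,
    out_dir: str | Path,
    filters: FilterConfig | None = None,
    tissue: str = "hepatocytes",
) -> tuple[MetaboNetwork, RunReport]:
    """Run the full cascade on in-memory pathways and annotation tables."""
    cfg = filters or FilterConfig()
    report = RunReport()
    out = Path(out_dir)
    written_paths: list[Path] = []

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            for path in written_paths:
                path.unlink(missing_ok=True)
            raise PipelineError(name, exc) from exc

    network = stage("build", lambda: build_network(pathways, seed_ids))
    report.record_stage("build", network)

    distances: DistanceMap = stage(
        "distance_filter", lambda: compute_seed_distances(network, cfg.distance_mode)
    )
    filtered = stage(
        "distance_filter",
        lambda: filter_by_distance(network, distances, cfg.max_steps),
    )
    report.record_removed(
        "distance_filter", network, filtered,
        f"more than {cfg.max_steps} steps from every seed",
    )
    report.record_stage("distance_filter", filtered)

    def _annotate():
        net, expr_rep = annotate_expression(filtered, tables.expression, tissue)
        net, prog_rep = annotate_prognosis(net, tables.prognosis, cfg.prognosis_alpha)
        net, bio_rep = annotate_biofluid(net, tables.biofluid)
        return net, expr_rep, prog_rep, bio_rep

    annotated, expr_rep, prog_rep, bio_rep = stage("annotate", _annotate)
    report.record_join("expression", expr_rep)
    report.record_join("prognosis", prog_rep)
    report.record_join("biofluid", bio_rep)
    report.record_stage("annotate", annotated)

    expression_map = dict(
        zip(
            tables.expression.loc[tables.expression["tissue"] == tissue, "gene_id"],
            tables.expression.loc[tables.expression["tissue"] == tissue, "value"],
        )
    )
    expressed = stage(
        "expression_filter",
        lambda: filter_unexpressed(annotated, expression_map, cfg.expression_threshold),
    )
    report.record_removed(
        "expression_filter", annotated, expressed,
        f"not expressed in {tissue} (value <= {cfg.expression_threshold})",
    )
    report.record_stage("expression_filter", expressed)

    pruned = stage(
        "prune",
        lambda: prune_structure(
            expressed, cfg.min_metabolite_neighbors, cfg.prune_to_fixpoint
        ),
    )
    report.record_removed(
        "prune", expressed, pruned,
        "disconnected from seeds or metabolic gene with too few metabolite neighbors",
    )
    report.record_stage("prune", pruned)

    def _export():
        out.mkdir(parents=True, exist_ok=True)
        written = [
            export_mod.write_node_table(pruned, out / "node_table.tsv", distances),
            export_mod.write_edge_table(pruned, out / "edge_table.tsv"),
            export_mod.write_sif(pruned, out / "network.sif"),
            export_mod.write_graphml(pruned, out / "network.graphml"),
        ]
        written_paths.extend(written)
        # names only, so the report is byte-identical across run locations
        report.outputs.extend(p.name for p in written)
        return written

    stage("export", _export)
    report.outputs.append("report.json")
    (out / "report.json").write_text(report.to_json() + "\n", encoding="utf-8")
    return pruned, report


def run_pipeline(config: RunConfig) -> tuple[MetaboNetwork, RunReport]:
    """Run the full cascade from files on disk (see :class:`RunConfig`)."""
    try:
        pathways = [read_kgml(p) for p in config.pathway_paths]
        tables = load_annotation_tables(
            config.expression_path, config.prognosis_path, config.biofluid_path
        )
    except Exception as exc:  # noqa: BLE001
        raise PipelineError("load", exc) from exc
    return run_pipeline_from_objects(
        pathways,
        tables,
        config.seed_ids,
        config.out_dir,
        filters=config.filters,
        tissue=config.tissue,
    )
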