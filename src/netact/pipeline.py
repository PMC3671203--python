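"""End-to-end orchestration: normalize -> activity -> cluster -> evaluate -> diff.

`run_pipeline` drives the whole analysis from a `PipelineConfig` and writes a
report directory of TSV/Newick/JSON artifacts plus a provenance record of
every switch that affects the numbers.  Subcluster selection for the
differential step is always an explicit, reproducible specification (a tree
cut plus a cluster id, or an explicit sample list) — never interactive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from . import __version__
from .activity import compute_module_activity, distribution_summary, standardize
from .cluster import (
    bicluster,
    cut_tree,
    export_newick,
    kmeans_correlation,
    select_k,
)
from .differential import (
    GroupComparison,
    differential_scores,
    module_gene_drilldown,
    subnetwork_export,
    top_fraction,
)
from .evaluate import evaluate_clustering
from .expression import (
    collapse_probes,
    consolidate_annotations,
    filter_annotated_samples,
    log2_transform,
    quantile_normalize,
    read_annotations_tsv,
    read_expression_tsv,
    read_probe_map_tsv,
)
from .network import GeneSignature, load_network

logger = logging.getLogger("netact")

__all__ = ["PipelineConfig", "run_pipeline", "run_signature_mode"]


@dataclass
class PipelineConfig:
    """Declarative description of one pipeline run (YAML/JSON loadable)."""

    network_membership: str
    network_edges: str
    expression: str
    annotations: str
    out_dir: str
    probe_map: str | None = None
    # normalization
    quantile: bool = True
    log2: bool = False
    # clustering
    distance: str = "pearson"
    k: int | None = 2
    k_range: tuple[int, int] | None = None
    n_restarts: int = 100
    seed: int = 0
    # evaluation
    required_annotations: list[str] = field(default_factory=list)
    consolidation: Mapping[str, Mapping[str, str]] = field(default_factory=dict)
    yates: bool = True
    # differential
    fraction: float = 0.15
    subcluster_k: int | None = None  # cut the sample dendrogram into this many
    subcluster_id: int | None = None  # ... and take this cluster as group A
    subcluster_samples: str | None = None  # or an explicit sample-list file
    drilldown_modules: list[str] = field(default_factory=list)
    min_genes: int = 1

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)  # YAML is a JSON superset
        if "k_range" in data and data["k_range"] is not None:
            data["k_range"] = tuple(data["k_range"])
        return cls(**data)

    def provenance(self) -> dict:
        record = asdict(self)
        record["netact_version"] = __version__
        return record


def _prepare(cfg: PipelineConfig):
    """Shared loading + normalization front end; returns (expr, annotations, net)."""
    net = load_network(cfg.network_membership, cfg.network_edges)
    expr = read_expression_tsv(cfg.expression)
    logger.info("loaded expression: %d features x %d samples", *expr.shape)
    annotations = read_annotations_tsv(cfg.annotations)
    if cfg.consolidation:
        annotations = consolidate_annotations(annotations, cfg.consolidation)
    if cfg.probe_map:
        expr = collapse_probes(expr, read_probe_map_tsv(cfg.probe_map))
        logger.info("collapsed probes: %d genes", expr.shape[0])
    if cfg.quantile:
        expr = quantile_normalize(expr)
    if cfg.log2:
        expr = log2_transform(expr)
    if cfg.required_annotations:
        expr, annotations = filter_annotated_samples(
            expr, annotations, cfg.required_annotations
        )
        logger.info("fully annotated samples retained: %d", expr.shape[1])
    return expr, annotations, net


def _cluster_evaluate_diff(
    features: pd.DataFrame,
    annotations: pd.DataFrame,
    cfg: PipelineConfig,
    net,
    out: Path,
    expr: pd.DataFrame | None = None,
) -> None:
    """Cluster a feature matrix, evaluate vs annotations, run differential."""
    row_dend, col_dend, ordered = bicluster(features, method=cfg.distance)
    (out / "samples.nwk").write_text(export_newick(col_dend))
    (out / "features.nwk").write_text(export_newick(row_dend))
    ordered.to_csv(out / "ordered_standardized.tsv", sep="\t")

    std, flagged = standardize(features)
    if flagged:
        logger.info("constant features flagged during standardization: %s", flagged)

    if cfg.k_range is not None:
        report = select_k(
            std, cfg.k_range, method=cfg.distance, seed=cfg.seed,
            n_restarts=cfg.n_restarts,
        )
        k = report.chosen_k
        pd.Series(report.silhouette_by_k, name="avg_silhouette").rename_axis(
            "k"
        ).to_csv(out / "silhouette_by_k.tsv", sep="\t")
        logger.info("silhouette-selected k = %d", k)
    else:
        k = cfg.k or 2

    km = kmeans_correlation(
        std, k, n_restarts=cfg.n_restarts, seed=cfg.seed, method=cfg.distance
    )
    km.assignments.rename_axis("sample_id").to_frame().to_csv(
        out / "kmeans_assignments.tsv", sep="\t"
    )

    markers = cfg.required_annotations or list(annotations.columns)
    report = evaluate_clustering(km.assignments, annotations, markers, yates=cfg.yates)
    report.to_csv(out / "evaluation.tsv", sep="\t", index=False)
    report.to_json(out / "evaluation.json", orient="records", indent=2)

    cmp = _subcluster_comparison(cfg, col_dend)
    if cmp is not None:
        table = top_fraction(
            differential_scores(features, cmp), fraction=cfg.fraction
        )
        table.table.rename_axis("item").to_csv(out / "differential.tsv", sep="\t")
        nodes, edges = subnetwork_export(net, table)
        nodes.to_csv(out / "subnetwork_nodes.tsv", sep="\t", index=False)
        edges.to_csv(out / "subnetwork_edges.tsv", sep="\t", index=False)
        if cfg.drilldown_modules and expr is not None:
            genes, skipped = module_gene_drilldown(
                net, expr, cmp, cfg.drilldown_modules, fraction=cfg.fraction
            )
            genes.table.rename_axis("gene").to_csv(
                out / "differential_genes.tsv", sep="\t"
            )
            if skipped:
                logger.warning("drilldown modules with no measured gene: %s", skipped)


def _subcluster_comparison(
    cfg: PipelineConfig, col_dend
) -> GroupComparison | None:
    if cfg.subcluster_samples:
        listed = [
            line.strip()
            for line in Path(cfg.subcluster_samples).read_text().splitlines()
            if line.strip()
        ]
        universe = set(col_dend.ids)
        group_a = frozenset(s for s in listed if s in universe)
        if not group_a:
            raise ValueError("no listed subcluster sample found in the matrix")
        return GroupComparison(
            group_a=group_a, group_b=frozenset(universe - group_a), label="sample-list"
        )
    if cfg.subcluster_k is not None and cfg.subcluster_id is not None:
        labels = cut_tree(col_dend, cfg.subcluster_k)
        return GroupComparison.from_labels(
            labels, cfg.subcluster_id,
            label=f"cut_k{cfg.subcluster_k}_cluster{cfg.subcluster_id}",
        )
    return None


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Run the full module-activity analysis; returns the report directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    stage = "setup"
    try:
        stage = "load+normalize"
        expr, annotations, net = _prepare(cfg)
        expr.rename_axis("gene").to_csv(out / "normalized_expression.tsv", sep="\t")

        stage = "module activity"
        activity = compute_module_activity(expr, net, min_genes=cfg.min_genes)
        activity.values.rename_axis("module").to_csv(out / "activity.tsv", sep="\t")
        activity.coverage.to_csv(out / "coverage.tsv", sep="\t")
        logger.info(
            "module activity: %d modules x %d samples", *activity.values.shape
        )

        stage = "distribution summary"
        network_expr = expr.loc[sorted(set(expr.index) & net.genes)]
        if (activity.values.to_numpy() > 0).all() and (
            network_expr.to_numpy() > 0
        ).all():
            distribution_summary(activity.values, network_expr).to_csv(
                out / "distribution_summary.tsv", sep="\t", index=False
            )

        stage = "cluster/evaluate/differential"
        _cluster_evaluate_diff(activity.values, annotations, cfg, net, out, expr=expr)

        stage = "provenance"
        (out / "provenance.json").write_text(json.dumps(cfg.provenance(), indent=2))
    except Exception as exc:
        failed_marker.write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    return out


def run_signature_mode(
    cfg: PipelineConfig, signature: GeneSignature | None = None
) -> Path:
    """Run the same pipeline on raw gene features instead of module activity.

    With a signature, features are the signature genes present in the matrix;
    without one, all network genes ("network genes" mode).  At least two
    signature genes must be measured.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr, annotations, net = _prepare(cfg)
    wanted = signature.genes if signature is not None else net.genes
    upper_index = expr.index.astype(str).str.upper()
    mask = upper_index.isin({g.upper() for g in wanted})
    features = expr.loc[mask]
    if features.shape[0] < 2:
        unmatched = sorted({g.upper() for g in wanted} - set(upper_index))
        raise ValueError(
            f"fewer than 2 signature genes measured; unmatched: {unmatched[:20]}"
        )
    label = signature.name if signature is not None else "network_genes"
    logger.info("signature mode %r: %d gene features", label, features.shape[0])
    _cluster_evaluate_diff(features, annotations, cfg, net, out, expr=expr)
    record = cfg.provenance()
    record["feature_mode"] = label
    (out / "provenance.json").write_text(json.dumps(record, indent=2))
    return out
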