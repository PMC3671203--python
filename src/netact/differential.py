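"""Differential module activity between a subcluster and all other samples.

For each item (module or gene) the two group means are computed on the
analysis (intensity) scale; the score is ``log2 |mean_a - mean_b|`` with the
sign of the difference stored separately as a direction.  The top fraction
(default 15%) of scores per dataset defines the selected set and its
threshold; a module is *cross-dataset consistent* when it is selected in both
datasets with the same direction.  Selection is a rank cutoff, not a
significance test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import SignalingNetwork

__all__ = [
    "GroupComparison",
    "DifferentialTable",
    "differential_scores",
    "top_fraction",
    "cross_dataset",
    "module_gene_drilldown",
    "subnetwork_export",
]


@dataclass(frozen=True)
class GroupComparison:
    """A subcluster of interest (group_a) versus all other samples (group_b)."""

    group_a: frozenset[str]
    group_b: frozenset[str]
    label: str = ""

    def __post_init__(self) -> None:
        if not self.group_a or not self.group_b:
            raise ValueError("both groups must be non-empty")
        if self.group_a & self.group_b:
            raise ValueError("groups overlap")

    @classmethod
    def from_labels(
        cls, labels: pd.Series, subcluster, label: str = ""
    ) -> "GroupComparison":
        """Build a comparison from cluster labels: samples with the given
        label form group_a, everything else group_b."""
        a = frozenset(labels.index[labels == subcluster].astype(str))
        b = frozenset(labels.index[labels != subcluster].astype(str))
        return cls(group_a=a, group_b=b, label=label or f"cluster_{subcluster}")


@dataclass
class DifferentialTable:
    """Per-item group means, signed differences, log2 scores and selection.

    ``table`` columns: mean_a, mean_b, signed_diff, score, direction (+1/-1),
    and — after `top_fraction` — selected (bool).  Items whose groups tie
    exactly (zero difference, log2 undefined) are excluded from scoring and
    listed in ``zero_diff_items``.
    """

    table: pd.DataFrame
    kind: str  # "module" or "gene"
    comparison_label: str = ""
    zero_diff_items: list[str] = field(default_factory=list)
    threshold: float | None = None
    fraction: float | None = None

    @property
    def selected_items(self) -> list[str]:
        if "selected" not in self.table.columns:
            raise ValueError("run top_fraction first")
        return list(self.table.index[self.table["selected"]])


def differential_scores(
    matrix: pd.DataFrame, cmp: GroupComparison, kind: str = "module"
) -> DifferentialTable:
    """Score every row of an activity or expression matrix for a comparison.

    Both groups need at least 2 samples present in the matrix.
    """
    cols = set(map(str, matrix.columns))
    a = sorted(cmp.group_a & cols)
    b = sorted(cmp.group_b & cols)
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"each group needs >= 2 samples in the matrix (got {len(a)} and {len(b)})"
        )
    mean_a = matrix[a].mean(axis=1)
    mean_b = matrix[b].mean(axis=1)
    signed = mean_a - mean_b
    nonzero = signed != 0
    zero_items = [str(i) for i in matrix.index[~nonzero]]
    table = pd.DataFrame(
        {
            "mean_a": mean_a[nonzero],
            "mean_b": mean_b[nonzero],
            "signed_diff": signed[nonzero],
            "score": np.log2(np.abs(signed[nonzero])),
            "direction": np.sign(signed[nonzero]).astype(int),
        }
    )
    if table.empty:
        raise ValueError("no item with a non-zero group difference")
    return DifferentialTable(
        table=table,
        kind=kind,
        comparison_label=cmp.label,
        zero_diff_items=zero_items,
    )


def top_fraction(table: DifferentialTable, fraction: float = 0.15) -> DifferentialTable:
    """Flag the top fraction of scores; ties at the cutoff are all included.

    ``ceil(fraction * n_scored)`` items are selected (so the selection is
    non-empty for any positive fraction); the threshold is the smallest
    selected score.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    scores = table.table["score"]
    n_sel = math.ceil(fraction * len(scores))
    threshold = float(scores.sort_values(ascending=False).iloc[n_sel - 1])
    out = table.table.copy()
    out["selected"] = out["score"] >= threshold
    out["threshold"] = threshold
    return DifferentialTable(
        table=out,
        kind=table.kind,
        comparison_label=table.comparison_label,
        zero_diff_items=list(table.zero_diff_items),
        threshold=threshold,
        fraction=fraction,
    )


def cross_dataset(
    table_1: DifferentialTable, table_2: DifferentialTable
) -> pd.DataFrame:
    """Join two per-dataset differential tables and flag consistent items.

    An item is consistent iff selected (top fraction) in BOTH datasets with
    the same direction.  Items scored in only one dataset appear with
    ``in_both = False`` and ``consistent = False``.
    """
    for t in (table_1, table_2):
        if t.threshold is None:
            raise ValueError("apply top_fraction to both tables first")
    cols = ["score", "direction", "selected"]
    joined = table_1.table[cols].join(
        table_2.table[cols], how="outer", lsuffix="_1", rsuffix="_2"
    )
    if joined[["score_1"]].notna().to_numpy().sum() == 0 or not (
        joined["score_1"].notna() & joined["score_2"].notna()
    ).any():
        raise ValueError("the two tables share no scored items")
    joined["in_both"] = joined["score_1"].notna() & joined["score_2"].notna()
    joined["consistent"] = (
        joined["in_both"]
        & joined["selected_1"].fillna(False).astype(bool)
        & joined["selected_2"].fillna(False).astype(bool)
        & (joined["direction_1"] == joined["direction_2"])
    )
    joined["threshold_1"] = table_1.threshold
    joined["threshold_2"] = table_2.threshold
    return joined


def module_gene_drilldown(
    net: SignalingNetwork,
    expr: pd.DataFrame,
    cmp: GroupComparison,
    module_names: list[str],
    fraction: float = 0.15,
) -> tuple[DifferentialTable, list[str]]:
    """Gene-level differential table for the member genes of named modules.

    Gene scores and the top-fraction threshold are computed over *all*
    network genes measured in the matrix (the dataset-level gene cutoff), then
    restricted to the union of the named modules' genes; each gene is tagged
    with the module(s) it belongs to.  Modules with no measured gene are
    returned in the skipped list.
    """
    unknown = [m for m in module_names if m not in net.modules]
    if unknown:
        raise KeyError(f"unknown modules: {unknown}")
    index_upper = expr.index.astype(str).str.strip().str.upper()
    expr_u = expr.set_axis(index_upper, axis=0)
    measured_network_genes = sorted(net.genes & set(expr_u.index))
    if not measured_network_genes:
        raise ValueError("no network gene measured in the matrix")
    gene_table = top_fraction(
        differential_scores(expr_u.loc[measured_network_genes], cmp, kind="gene"),
        fraction=fraction,
    )
    gene_to_mods = net.gene_to_modules()
    skipped: list[str] = []
    member_genes: set[str] = set()
    for name in module_names:
        measured = net.modules[name].genes & set(expr_u.index)
        if not measured:
            skipped.append(name)
        member_genes |= measured
    rows = gene_table.table.loc[sorted(member_genes & set(gene_table.table.index))].copy()
    rows["modules"] = [
        ";".join(sorted(set(gene_to_mods[g]) & set(module_names))) for g in rows.index
    ]
    return (
        DifferentialTable(
            table=rows,
            kind="gene",
            comparison_label=cmp.label,
            zero_diff_items=[g for g in gene_table.zero_diff_items if g in member_genes],
            threshold=gene_table.threshold,
            fraction=fraction,
        ),
        skipped,
    )


def subnetwork_export(
    net: SignalingNetwork, table: DifferentialTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables for the selected modules, for external viewers.

    Nodes carry score/direction attributes; edges are the network edges whose
    endpoints are both selected.
    """
    selected = set(table.selected_items)
    nodes = table.table.loc[sorted(selected), ["score", "direction", "selected"]].copy()
    nodes.index.name = "node"
    edges = pd.DataFrame(
        [
            {"source": e.source, "target": e.target, "sign": e.sign}
            for e in net.edges
            if e.source in selected and e.target in selected
        ],
        columns=["source", "target", "sign"],
    )
    return nodes.reset_index(), edges
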