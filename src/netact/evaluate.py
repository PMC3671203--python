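"""Cluster-vs-annotation association via contingency tables and chi-square.

Each clustering is scored against each clinical marker by cross-tabulating
cluster membership with the marker's categories and testing independence with
a Pearson chi-square test.  Yates continuity correction is applied to 2x2
tables by default — the convention under which the published cohort tables'
p-values reproduce — and can be switched off (``yates=False``), e.g. for
calibration studies where the deliberate conservativeness of the correction
is unwanted.  No multiple-testing adjustment is applied across markers; raw
p-values are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

__all__ = [
    "ContingencyTable",
    "ChiSquareResult",
    "contingency",
    "chi_square_test",
    "evaluate_clustering",
]

#: expected-count threshold below which a warning (not an error) is emitted
SMALL_EXPECTED = 5.0


@dataclass
class ContingencyTable:
    """Annotation categories (rows) x cluster ids (columns) counts."""

    counts: pd.DataFrame
    annotation: str
    n_missing: int = 0

    def __post_init__(self) -> None:
        values = self.counts.to_numpy()
        if (values < 0).any() or not np.issubdtype(values.dtype, np.integer):
            raise ValueError("contingency counts must be non-negative integers")
        if (values.sum(axis=1) == 0).any() or (values.sum(axis=0) == 0).any():
            raise ValueError("contingency table has an all-zero row or column")

    @property
    def n(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    correction_applied: bool


def contingency(
    cluster_labels: pd.Series, annotations: pd.DataFrame, annotation_name: str
) -> ContingencyTable:
    """Cross-tabulate cluster membership against one clinical marker.

    Samples with a MISSING value are excluded and counted in ``n_missing``.
    Raises if fewer than two categories or two clusters remain.
    """
    if annotation_name not in annotations.columns:
        raise KeyError(f"annotation {annotation_name!r} not present")
    shared = [s for s in cluster_labels.index if s in annotations.index]
    if not shared:
        raise ValueError("cluster labels and annotations share no sample ids")
    labels = cluster_labels.loc[shared]
    marker = annotations.loc[shared, annotation_name]
    present = marker.notna()
    table = pd.crosstab(marker[present], labels[present])
    if table.shape[0] < 2:
        raise ValueError(
            f"annotation {annotation_name!r}: fewer than 2 categories after "
            "filtering (all samples one category?)"
        )
    if table.shape[1] < 2:
        raise ValueError(
            f"annotation {annotation_name!r}: fewer than 2 clusters after filtering"
        )
    table.index.name = annotation_name
    table.columns.name = "cluster"
    return ContingencyTable(
        counts=table, annotation=annotation_name, n_missing=int((~present).sum())
    )


def chi_square_test(table: ContingencyTable, yates: bool = True) -> ChiSquareResult:
    """Pearson chi-square test of independence.

    Continuity correction is applied iff the table is 2x2 and ``yates`` is
    True.  Zero expected counts are an error (merge categories first); small
    expected counts (< 5) only warn.
    """
    counts = table.counts.to_numpy()
    total = counts.sum()
    expected = np.outer(counts.sum(axis=1), counts.sum(axis=0)) / total
    if (expected == 0).any():
        raise ValueError(
            f"annotation {table.annotation!r}: zero expected count; "
            "merge sparse categories before testing"
        )
    if (expected < SMALL_EXPECTED).any():
        warnings.warn(
            f"annotation {table.annotation!r}: expected count below "
            f"{SMALL_EXPECTED}; chi-square approximation may be poor",
            stacklevel=2,
        )
    apply_correction = yates and counts.shape == (2, 2)
    stat, p, df, _ = chi2_contingency(counts, correction=apply_correction)
    return ChiSquareResult(
        statistic=float(stat),
        df=int(df),
        p_value=float(p),
        correction_applied=apply_correction,
    )


def evaluate_clustering(
    cluster_labels: pd.Series,
    annotations: pd.DataFrame,
    annotation_names: list[str],
    yates: bool = True,
) -> pd.DataFrame:
    """Score one clustering against several clinical markers.

    Returns a long-format report with one row per (annotation, category):
    per-cluster counts plus the marker-level chi-square statistic, df and
    p-value (repeated on each of the marker's rows, mirroring the usual
    published layout).  A marker whose table is degenerate is reported with an
    ``error`` message instead of aborting the run.
    """
    rows: list[dict] = []
    for name in annotation_names:
        try:
            table = contingency(cluster_labels, annotations, name)
            result = chi_square_test(table, yates=yates)
        except (ValueError, KeyError) as exc:
            rows.append({"annotation": name, "category": None, "error": str(exc)})
            continue
        for category, counts in table.counts.iterrows():
            row: dict = {"annotation": name, "category": category, "error": None}
            for cluster_id, count in counts.items():
                row[f"cluster_{cluster_id}"] = int(count)
            row.update(
                chi2=result.statistic,
                df=result.df,
                p_value=result.p_value,
                correction=result.correction_applied,
                n_missing=table.n_missing,
            )
            rows.append(row)
    return pd.DataFrame(rows)
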