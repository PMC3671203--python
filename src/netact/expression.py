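"""Expression-matrix and clinical-annotation I/O and preprocessing.

Expression data are genes-(or probes)-by-samples matrices of positive
hybridization intensities, held as pandas DataFrames with unique row and
column labels and no missing values (missingness is rejected at load, not
imputed).  Clinical annotations are one categorical column per marker, indexed
by sample id, with empty cells meaning MISSING.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionFormatError",
    "read_expression_tsv",
    "read_annotations_tsv",
    "read_probe_map_tsv",
    "validate_expression",
    "quantile_normalize",
    "collapse_probes",
    "filter_annotated_samples",
    "consolidate_annotations",
]

MISSING = np.nan


class ExpressionFormatError(ValueError):
    """Raised for malformed expression / annotation / probe-map files."""


def validate_expression(expr: pd.DataFrame, positive: bool = False) -> pd.DataFrame:
    """Enforce the expression-matrix invariants; return the frame unchanged."""
    if expr.shape[0] == 0 or expr.shape[1] == 0:
        raise ExpressionFormatError("expression matrix has no data")
    if expr.index.has_duplicates:
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ExpressionFormatError(f"duplicate feature ids: {dups[:5]}")
    if expr.columns.has_duplicates:
        dups = expr.columns[expr.columns.duplicated()].unique().tolist()
        raise ExpressionFormatError(f"duplicate sample ids: {dups[:5]}")
    values = expr.to_numpy()
    if not np.isfinite(values).all():
        i, j = np.argwhere(~np.isfinite(values))[0]
        raise ExpressionFormatError(
            f"non-finite value at feature {expr.index[i]!r}, sample {expr.columns[j]!r}"
        )
    if positive and (values < 0).any():
        i, j = np.argwhere(values < 0)[0]
        raise ExpressionFormatError(
            f"negative intensity at feature {expr.index[i]!r}, sample {expr.columns[j]!r}"
        )
    return expr


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a features x samples TSV (feature ids in column 1, sample ids in
    the header row, numeric body) into a validated DataFrame.

    A non-numeric cell raises with the offending row/column named.
    """
    try:
        raw = pd.read_csv(path, sep="\t", index_col=0, comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        raise ExpressionFormatError(f"{path}: empty file") from None
    # check the header before pandas de-duplicates repeated column names
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                header = [c.strip() for c in line.rstrip("\n").split("\t")[1:]]
                break
        else:
            header = []
    if len(set(header)) != len(header):
        dups = sorted({c for c in header if header.count(c) > 1})
        raise ExpressionFormatError(f"{path}: duplicate sample ids {dups}")
    if raw.shape[0] == 0 or raw.shape[1] == 0:
        raise ExpressionFormatError(f"{path}: matrix body is empty")
    expr = raw.apply(pd.to_numeric, errors="coerce")
    bad = expr.isna() & raw.notna()
    if bad.to_numpy().any():
        i, j = np.argwhere(bad.to_numpy())[0]
        raise ExpressionFormatError(
            f"{path}: non-numeric cell {raw.iat[i, j]!r} at "
            f"feature {raw.index[i]!r}, sample {raw.columns[j]!r}"
        )
    if expr.isna().to_numpy().any():
        i, j = np.argwhere(expr.isna().to_numpy())[0]
        raise ExpressionFormatError(
            f"{path}: missing value at feature {raw.index[i]!r}, "
            f"sample {raw.columns[j]!r}"
        )
    expr.index = expr.index.astype(str).str.strip()
    expr.columns = expr.columns.astype(str).str.strip()
    return validate_expression(expr)


def read_annotations_tsv(path: str | Path) -> pd.DataFrame:
    """Read a clinical-annotation TSV: `sample_id` column plus one column per
    annotation; empty cells are MISSING."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if "sample_id" not in df.columns:
        raise ExpressionFormatError(f"{path}: missing 'sample_id' column")
    df = df.set_index("sample_id")
    if df.index.has_duplicates:
        raise ExpressionFormatError(f"{path}: duplicate sample ids")
    return df.apply(lambda c: c.str.strip() if c.dtype == object else c)


def read_probe_map_tsv(path: str | Path) -> dict[str, str]:
    """Read a `probe  gene` TSV into a probe -> symbol map (many-to-one)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    for col in ("probe", "gene"):
        if col not in df.columns:
            raise ExpressionFormatError(f"{path}: missing '{col}' column")
    df = df.dropna(subset=["gene"])
    mapping: dict[str, str] = {}
    for probe, gene in zip(df["probe"], df["gene"]):
        probe = str(probe).strip()
        gene = str(gene).strip().upper()
        if probe in mapping and mapping[probe] != gene:
            raise ExpressionFormatError(
                f"{path}: probe {probe!r} mapped to more than one symbol"
            )
        mapping[probe] = gene
    return mapping


def quantile_normalize(expr: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize samples so every column shares one value multiset.

    The reference distribution is the vector of row means of the column-sorted
    matrix.  Within each column ranks are preserved; tied values receive the
    mean of the reference values over their rank span, so the map is
    idempotent up to floating error.
    """
    validate_expression(expr)
    if expr.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    values = expr.to_numpy(dtype=float)
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        mapped = np.empty_like(col)
        mapped[order] = reference
        # average the reference over runs of tied input values
        out[:, j] = pd.Series(mapped).groupby(col).transform("mean").to_numpy()
    return pd.DataFrame(out, index=expr.index, columns=expr.columns)


def collapse_probes(
    expr: pd.DataFrame, probe_map: Mapping[str, str], method: str = "median"
) -> pd.DataFrame:
    """Collapse probe rows to one row per gene symbol.

    method="median": per-sample median across a gene's probes (default, in
    keeping with the pipeline's median-based aggregation); "max_mean": keep
    the single probe with the largest row mean.  Unmapped probes are dropped.
    """
    if not probe_map:
        raise ValueError("empty probe map")
    if method not in {"median", "max_mean"}:
        raise ValueError(f"unknown collapse method {method!r}")
    genes = expr.index.to_series().map(lambda p: probe_map.get(str(p)))
    mapped = expr.loc[genes.notna().to_numpy()]
    if mapped.shape[0] == 0:
        raise ValueError("no probe in the matrix is covered by the probe map")
    symbols = genes.dropna()
    if method == "median":
        collapsed = mapped.groupby(symbols, sort=True).median()
    else:
        means = mapped.mean(axis=1)
        best = means.groupby(symbols, sort=True).idxmax()
        collapsed = mapped.loc[best]
        collapsed.index = best.index
    collapsed.index.name = expr.index.name
    return collapsed


def filter_annotated_samples(
    expr: pd.DataFrame, annotations: pd.DataFrame, required: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep only samples annotated for *all* required clinical markers.

    Sample order is preserved.  Raises if a required marker is undeclared or if
    no sample survives.
    """
    missing_cols = [a for a in required if a not in annotations.columns]
    if missing_cols:
        raise KeyError(f"annotations not declared: {missing_cols}")
    keep = [
        s
        for s in expr.columns
        if s in annotations.index
        and not annotations.loc[s, required].isna().any()
    ] if required else list(expr.columns)
    if not keep:
        raise ValueError(
            f"no sample is fully annotated for {required}; cannot proceed"
        )
    return expr[keep], annotations.loc[keep]


def consolidate_annotations(
    annotations: pd.DataFrame, mapping: Mapping[str, Mapping[str, str]]
) -> pd.DataFrame:
    """Recode annotation categories via a per-marker mapping table.

    E.g. ``{"stage": {"I": "low", "II": "low", "III": "high", "IV": "high"}}``
    consolidates tumor stage to low/high.  Values absent from the mapping are
    left unchanged; MISSING stays MISSING.
    """
    out = annotations.copy()
    for marker, table in mapping.items():
        if marker not in out.columns:
            raise KeyError(f"annotation {marker!r} not present")
        out[marker] = out[marker].map(
            lambda v: table.get(v, v) if isinstance(v, str) else v
        )
    return out


def log2_transform(expr: pd.DataFrame, offset: float = 0.0) -> pd.DataFrame:
    """log2(x + offset); requires strictly positive arguments."""
    values = expr.to_numpy(dtype=float) + offset
    if (values <= 0).any():
        raise ValueError("log2 transform needs strictly positive values "
                         "(consider an offset)")
    return pd.DataFrame(np.log2(values), index=expr.index, columns=expr.columns)
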