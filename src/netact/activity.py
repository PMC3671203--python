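"""Network module activity: per-sample median expression of module genes.

The activity of a module in a sample is the median of the expression values of
the module's *measured* genes (genes present in the matrix) in that sample.
Medians of even counts use the midpoint of the two central values.  Being a
median, each activity value lies inside the range spanned by the member genes,
so the activity distribution is a slightly confined version of the pooled
member-gene expression distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import SignalingNetwork

__all__ = [
    "ModuleActivity",
    "compute_module_activity",
    "standardize",
    "distribution_summary",
]


@dataclass
class ModuleActivity:
    """Modules x samples activity matrix plus per-module gene coverage.

    ``coverage`` has one row per *gene-bearing* network module with columns
    ``n_measured`` and ``n_total``; modules with fewer than ``min_genes``
    measured genes are absent from ``values`` but present in ``coverage``.
    """

    values: pd.DataFrame
    coverage: pd.DataFrame

    @property
    def module_names(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


def compute_module_activity(
    expr: pd.DataFrame, net: SignalingNetwork, min_genes: int = 1
) -> ModuleActivity:
    """Score every gene-bearing module as the median of its measured genes.

    ``expr`` rows must be gene symbols (upper-cased for matching).  Gene-less
    Effector connector modules are never scored.  Raises if no module reaches
    ``min_genes`` measured genes.
    """
    if min_genes < 1:
        raise ValueError("min_genes must be >= 1")
    index_upper = expr.index.astype(str).str.strip().str.upper()
    expr_u = expr.set_axis(index_upper, axis=0)
    # a symbol duplicated after case-folding would make row lookup ambiguous
    if expr_u.index.has_duplicates:
        dups = expr_u.index[expr_u.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate gene symbols after case folding: {dups[:5]}")

    rows: dict[str, np.ndarray] = {}
    cov_rows = []
    for mod in net.scoreable_modules():
        measured = sorted(
            g for g in {str(x).strip().upper() for x in mod.genes}
            if g in expr_u.index
        )
        cov_rows.append(
            {"module": mod.name, "n_measured": len(measured), "n_total": len(mod.genes)}
        )
        if len(measured) >= min_genes:
            rows[mod.name] = np.median(expr_u.loc[measured].to_numpy(), axis=0)
    if not rows:
        raise ValueError(
            f"no module has >= {min_genes} measured genes in this matrix"
        )
    values = pd.DataFrame.from_dict(rows, orient="index", columns=expr.columns)
    coverage = pd.DataFrame(cov_rows).set_index("module")
    return ModuleActivity(values=values, coverage=coverage)


def standardize(matrix: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Scale each feature row to mean 0 and sample standard deviation 1.

    Uses the n-1 denominator.  Constant rows (sd = 0) become all-zero and are
    returned in the flagged list rather than propagating NaNs.
    """
    if matrix.shape[1] < 2:
        raise ValueError("standardization needs at least 2 samples")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    constant = (sd[:, 0] == 0)
    sd[constant, :] = 1.0
    out = (values - mean) / sd
    out[constant, :] = 0.0
    flagged = [str(f) for f in matrix.index[constant]]
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns), flagged


def distribution_summary(
    activity: pd.DataFrame, expr: pd.DataFrame, bins: int = 50
) -> pd.DataFrame:
    """Compare the log10 distributions of module activity and gene expression.

    Returns a table with shared bin edges and per-series normalized masses
    (each series sums to 1), the tabular counterpart of the usual
    activity-vs-expression histogram overlay.  All values must be positive.
    """
    a = activity.to_numpy(dtype=float).ravel()
    e = expr.to_numpy(dtype=float).ravel()
    if (a <= 0).any() or (e <= 0).any():
        raise ValueError(
            "distribution_summary needs strictly positive values; apply an "
            "offset or normalize to the intensity scale first"
        )
    la, le = np.log10(a), np.log10(e)
    lo = min(la.min(), le.min())
    hi = max(la.max(), le.max())
    if lo == hi:  # constant input: a single occupied bin
        lo, hi = lo - 0.5, hi + 0.5
    edges = np.linspace(lo, hi, bins + 1)
    mass_a, _ = np.histogram(la, bins=edges)
    mass_e, _ = np.histogram(le, bins=edges)
    return pd.DataFrame(
        {
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "activity_mass": mass_a / mass_a.sum(),
            "expression_mass": mass_e / mass_e.sum(),
        }
    )
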