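"""Synthetic expression cohorts with planted module-activity structure.

The generator emulates the statistical structure the stratification analysis
assumes: positive microarray-like intensities (lognormal marginals), shared
within-module variation, group-specific module-activity shifts, and clinical
labels stochastically concordant with group membership.

Generative model, per gene g and sample s (everything on the log2 scale):

    b_g                ~ Normal(baseline_log2_mean, baseline_log2_sd)
    f_{m,s}            ~ Normal(effect[group(s), m], tau)        per module m
    log2 x_{g,s}       = b_g + sum over modules carrying g + Normal(0, sigma)
    x_{g,s}            = 2 ** log2 x_{g,s}

Carrier genes of a module receive its shifted factor ``f``; a configurable
fraction of a differential module's genes are *non-carriers* and share a
separate null factor Normal(0, tau) instead — so a planted module shift is
driven by only part of its gene set, as observed in real cohorts.  Genes in
no module (optional background genes) get baseline plus noise only; a gene in
several modules sums their factors.  Clinical labels take the group's
category with probability ``concordance`` and another category otherwise.

Everything is drawn from one seeded stream in a fixed order, so a dataset is
bit-for-bit reproducible from its seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .network import SignalingNetwork, fixture_network

__all__ = [
    "AnnotationSpec",
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_dataset",
    "default_scenario",
    "write_dataset",
]


@dataclass(frozen=True)
class AnnotationSpec:
    """One clinical marker: per-group category plus label fidelity.

    ``categories[i]`` is the category that group i "should" carry;
    ``concordance`` is the probability the drawn label actually agrees.
    """

    categories: tuple[str, ...]
    concordance: float

    def __post_init__(self) -> None:
        if not 0.5 <= self.concordance <= 1.0:
            raise ValueError("concordance must lie in [0.5, 1]")


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of a synthetic cohort (see module docstring)."""

    groups: tuple[str, ...]
    group_sizes: tuple[int, ...]
    network: SignalingNetwork = field(default_factory=fixture_network)
    #: group name -> module name -> planted log2 activity shift (0 = null)
    effect_map: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    within_module_corr: float = 0.3  # tau, sd of the shared module factor
    gene_noise_sd: float = 0.4  # sigma, per-gene log2 noise
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.0
    #: fraction of a *differential* module's genes left as non-carriers;
    #: a single float or a per-module override map
    non_carrier_fraction: float | Mapping[str, float] = 0.3
    annotations: Mapping[str, AnnotationSpec] = field(default_factory=dict)
    n_background_genes: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) != len(self.group_sizes):
            raise ValueError("group_sizes length must equal number of groups")
        if len(set(self.groups)) != len(self.groups):
            raise ValueError("duplicate group names")
        if any(n < 1 for n in self.group_sizes):
            raise ValueError("group sizes must be positive")
        for sd in (self.within_module_corr, self.gene_noise_sd, self.baseline_log2_sd):
            if sd < 0:
                raise ValueError("standard deviations must be >= 0")
        for group in self.effect_map:
            if group not in self.groups:
                raise ValueError(f"effect_map group {group!r} not in groups")
            for module in self.effect_map[group]:
                if module not in self.network.modules:
                    raise ValueError(f"effect_map module {module!r} not in network")
        for spec in self.annotations.values():
            if len(spec.categories) != len(self.groups):
                raise ValueError("annotation needs one category per group")

    @property
    def n_samples(self) -> int:
        return int(sum(self.group_sizes))

    def effect(self, group: str, module: str) -> float:
        return float(self.effect_map.get(group, {}).get(module, 0.0))

    def noncarrier_fraction_for(self, module: str) -> float:
        if isinstance(self.non_carrier_fraction, Mapping):
            return float(self.non_carrier_fraction.get(module, 0.3))
        return float(self.non_carrier_fraction)


@dataclass
class SyntheticDataset:
    """A simulated cohort with its ground truth."""

    expr: pd.DataFrame  # genes x samples, positive intensities
    annotations: pd.DataFrame  # samples x markers
    groups: pd.Series  # sample id -> true group name
    carriers: dict[str, frozenset[str]]  # module -> carrier genes
    config: SimulationConfig


def simulate_dataset(
    config: SimulationConfig, seed: int | None = None
) -> SyntheticDataset:
    """Draw one cohort; ``seed`` overrides ``config.seed`` when given."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    net = config.network

    genes = sorted(net.genes)
    genes += [f"BG{i:04d}" for i in range(config.n_background_genes)]
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    n_samples = config.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n_samples)]
    group_of = np.repeat(np.arange(len(config.groups)), config.group_sizes)
    group_names = pd.Series(
        [config.groups[i] for i in group_of], index=sample_ids, name="group"
    )

    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, n_genes)
    log2x = baseline[:, None] + rng.normal(0.0, config.gene_noise_sd, (n_genes, n_samples))

    carriers: dict[str, frozenset[str]] = {}
    for mod in sorted(net.scoreable_modules(), key=lambda m: m.name):
        members = sorted(mod.genes)
        differential = any(
            config.effect(g, mod.name) != 0.0 for g in config.groups
        )
        if differential:
            n_out = int(round(config.noncarrier_fraction_for(mod.name) * len(members)))
            n_out = min(n_out, len(members) - 1)  # keep at least one carrier
            out_idx = rng.choice(len(members), size=n_out, replace=False)
            non_carriers = {members[i] for i in out_idx}
        else:
            non_carriers = set()
        carrier_genes = [g for g in members if g not in non_carriers]
        carriers[mod.name] = frozenset(carrier_genes)

        shift = np.array(
            [config.effect(config.groups[i], mod.name) for i in group_of]
        )
        factor = rng.normal(shift, config.within_module_corr)
        rows = [gene_pos[g] for g in carrier_genes]
        log2x[rows, :] += factor[None, :]
        if non_carriers:
            null_factor = rng.normal(0.0, config.within_module_corr, n_samples)
            rows = [gene_pos[g] for g in sorted(non_carriers)]
            log2x[rows, :] += null_factor[None, :]

    expr = pd.DataFrame(np.exp2(log2x), index=genes, columns=sample_ids)

    ann_cols: dict[str, list[str]] = {}
    for marker in sorted(config.annotations):
        spec = config.annotations[marker]
        labels = []
        for gi in group_of:
            truth = spec.categories[gi]
            if rng.random() < spec.concordance:
                labels.append(truth)
            else:
                others = [c for c in set(spec.categories) if c != truth]
                labels.append(others[rng.integers(len(others))] if others else truth)
        ann_cols[marker] = labels
    annotations = pd.DataFrame(ann_cols, index=pd.Index(sample_ids, name="sample_id"))

    return SyntheticDataset(
        expr=expr,
        annotations=annotations,
        groups=group_names,
        carriers=carriers,
        config=config if seed is None else replace(config, seed=seed),
    )


def default_scenario(name: str) -> SimulationConfig:
    """Named study conditions on the bundled fixture network.

    ``breast_like``
        Two groups, the smaller one flavored "high grade / ER-negative /
        HER2-negative": lower PDGFR and INSR upstream-module activity, higher
        AP1 / MAPK-downstream / NFkB-related activity.
    ``ovarian_like``
        Two groups, the smaller one flavored "low malignant potential":
        higher AP1, MAPK-Inhibitor and INSR-RTK activity, lower PDGFR-RTK and
        PDGFR-CoActivator activity.
    ``null``
        Two labeled groups with concordant annotations but no planted
        expression effect at all (calibration scenario).
    """
    if name == "breast_like":
        return SimulationConfig(
            groups=("other", "high_grade"),
            group_sizes=(68, 45),
            effect_map={
                "high_grade": {
                    "PDGFR-RTK": -1.5,
                    "PDGFR-CoActivator": -1.5,
                    "INSR-RTK": -1.5,
                    "INSR-Ligand": -1.5,
                    "AP1": 2.0,
                    "Downstream-MAPK": 1.5,
                    "NFkB-SignalingComplex": 1.0,
                    "NFkB-Inhibitor": 1.0,
                    "TGF/BMP-Adaptor": 1.0,
                }
            },
            annotations={
                "ER": AnnotationSpec(("pos", "neg"), 0.90),
                "HER2": AnnotationSpec(("pos", "neg"), 0.55),
                "grade": AnnotationSpec(("low", "high"), 0.80),
            },
        )
    if name == "ovarian_like":
        return SimulationConfig(
            groups=("other", "lmp"),
            group_sizes=(58, 25),
            # two-tier effects: AP1 / MAPK-Inhibitor carry the headline
            # shifts, the receptor-level modules a weaker secondary shift
            effect_map={
                "lmp": {
                    "AP1": 2.5,
                    "MAPK-Inhibitor": 2.5,
                    "INSR-RTK": 1.2,
                    "PDGFR-RTK": -1.2,
                    "PDGFR-CoActivator": -1.2,
                }
            },
            annotations={
                "type": AnnotationSpec(("malignant", "LMP"), 0.95),
                "stage": AnnotationSpec(("high", "low"), 0.80),
                "grade": AnnotationSpec(("high", "low"), 0.75),
            },
        )
    if name == "null":
        return SimulationConfig(
            groups=("g1", "g2"),
            group_sizes=(100, 100),
            effect_map={},
            annotations={
                "ER": AnnotationSpec(("pos", "neg"), 0.90),
                "HER2": AnnotationSpec(("pos", "neg"), 0.55),
                "grade": AnnotationSpec(("low", "high"), 0.80),
            },
        )
    raise ValueError(f"unknown scenario {name!r}")


def write_dataset(ds: SyntheticDataset, out_dir: str | Path) -> None:
    """Write a dataset in the TSV formats the pipeline consumes, plus truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ds.expr.rename_axis("gene").to_csv(out / "expression.tsv", sep="\t")
    ds.annotations.rename_axis("sample_id").to_csv(out / "annotations.tsv", sep="\t")
    ds.groups.rename_axis("sample_id").to_frame().to_csv(out / "truth_groups.tsv", sep="\t")
    echo = {
        "seed": ds.config.seed,
        "groups": list(ds.config.groups),
        "group_sizes": list(ds.config.group_sizes),
        "effect_map": {g: dict(m) for g, m in ds.config.effect_map.items()},
        "carriers": {m: sorted(gs) for m, gs in ds.carriers.items()},
    }
    (out / "truth.json").write_text(json.dumps(echo, indent=2))
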