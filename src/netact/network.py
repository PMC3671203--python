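"""Module-based signaling-network model.

A signaling network is represented as a set of named *modules* — gene sets
grouped by pathway (PDGFR, INSR, AP1, ...) and functional role (Ligand,
Receptor, Adaptor, ...) — connected by signed activation/inhibition edges.
Gene-less *Effector* connector nodes (``activeERK``, ``activeAKT``) join
downstream cascades to transcription-factor modules; they carry no activity
score.  Edges are carried for reporting and subnetwork export only; no signal
propagation is performed on them.

Gene identifiers are HGNC-style symbols, matched case-insensitively after
whitespace trimming.  A gene may belong to more than one module; the distinct
gene census deduplicates.
"""

from __future__ import annotations

import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

__all__ = [
    "ROLES",
    "NetworkModule",
    "ModuleEdge",
    "SignalingNetwork",
    "GeneSignature",
    "NetworkFormatError",
    "NetworkValidationError",
    "load_network",
    "write_network",
    "network_stats",
    "load_signature_gmt",
    "signature_network_overlap",
    "fixture_network",
]

#: Role vocabulary.  Extendable per network via ``extra_roles``.
ROLES = frozenset(
    {
        "Ligand",
        "Receptor",
        "Adaptor",
        "Downstream",
        "TranscriptionFactor",
        "CoActivator",
        "CoInhibitor",
        "Inhibitor",
        "Effector",
    }
)

EDGE_SIGNS = frozenset({"activation", "inhibition"})


class NetworkFormatError(ValueError):
    """Raised when a network or signature file does not match its format."""


class NetworkValidationError(ValueError):
    """Raised when file contents violate network invariants."""


def _norm_gene(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass(frozen=True)
class NetworkModule:
    """A named gene set with a pathway label and a functional role.

    ``genes`` may be empty only for Effector connector nodes.
    """

    name: str
    pathway: str
    role: str
    genes: frozenset[str] = field(default_factory=frozenset)

    @property
    def n_genes(self) -> int:
        return len(self.genes)


@dataclass(frozen=True)
class ModuleEdge:
    """A signed edge between two modules."""

    source: str
    target: str
    sign: str


class NetworkStats(NamedTuple):
    n_genes: int
    n_modules: int
    n_edges: int


@dataclass(frozen=True)
class GeneSignature:
    """A published discriminatory gene set (one GMT line)."""

    name: str
    genes: frozenset[str]


@dataclass
class SignalingNetwork:
    """Validated collection of modules and signed module-level edges."""

    modules: dict[str, NetworkModule]
    edges: list[ModuleEdge]
    provenance: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names = list(self.modules)
        if len(set(names)) != len(names):
            raise NetworkValidationError("duplicate module names")
        for name, mod in self.modules.items():
            if mod.name != name:
                raise NetworkValidationError(
                    f"module key {name!r} does not match module name {mod.name!r}"
                )
        for i, edge in enumerate(self.edges):
            for endpoint in (edge.source, edge.target):
                if endpoint not in self.modules:
                    raise NetworkValidationError(
                        f"edge row {i} ({edge.source} -> {edge.target}): "
                        f"unknown module {endpoint!r}"
                    )
            if edge.sign not in EDGE_SIGNS:
                raise NetworkValidationError(
                    f"edge row {i}: sign must be one of {sorted(EDGE_SIGNS)}, "
                    f"got {edge.sign!r}"
                )

    # -- gene-centric views -------------------------------------------------

    @property
    def genes(self) -> frozenset[str]:
        """Distinct gene symbols across all modules."""
        out: set[str] = set()
        for mod in self.modules.values():
            out |= mod.genes
        return frozenset(out)

    def gene_to_modules(self) -> dict[str, frozenset[str]]:
        """Inverse index gene -> names of modules containing it."""
        inv: dict[str, set[str]] = {}
        for mod in self.modules.values():
            for g in mod.genes:
                inv.setdefault(g, set()).add(mod.name)
        return {g: frozenset(ms) for g, ms in inv.items()}

    def scoreable_modules(self) -> list[NetworkModule]:
        """Modules carrying at least one gene (Effector connectors excluded)."""
        return [m for m in self.modules.values() if m.genes]


def load_network(
    membership_path: str | Path,
    edges_path: str | Path,
    extra_roles: Iterable[str] = (),
) -> SignalingNetwork:
    """Read a network from a membership TSV and a signed edge-list TSV.

    The membership file has columns ``gene  module  pathway  role``; a row with
    an empty gene field declares a gene-less module (Effector connector).  The
    edge file has columns ``source  target  sign`` with sign in
    {activation, inhibition}.  Lines starting with ``#`` are ignored.
    """
    roles = ROLES | {str(r) for r in extra_roles}
    mem = _read_tsv(membership_path, ["gene", "module", "pathway", "role"])
    edg = _read_tsv(edges_path, ["source", "target", "sign"], allow_empty=True)

    modules: dict[str, NetworkModule] = {}
    genes_by_module: dict[str, set[str]] = {}
    meta_by_module: dict[str, tuple[str, str]] = {}
    for row in mem.itertuples(index=False):
        name = str(row.module).strip()
        if not name:
            raise NetworkValidationError("membership row with empty module name")
        role = str(row.role).strip()
        if role not in roles:
            raise NetworkValidationError(
                f"module {name!r}: unknown role {role!r} "
                f"(known: {sorted(roles)})"
            )
        pathway = str(row.pathway).strip()
        if name in meta_by_module and meta_by_module[name] != (pathway, role):
            raise NetworkValidationError(
                f"module {name!r} declared with conflicting pathway/role"
            )
        meta_by_module[name] = (pathway, role)
        genes_by_module.setdefault(name, set())
        gene = "" if pd.isna(row.gene) else _norm_gene(row.gene)
        if gene:
            genes_by_module[name].add(gene)

    for name, (pathway, role) in meta_by_module.items():
        modules[name] = NetworkModule(
            name=name, pathway=pathway, role=role,
            genes=frozenset(genes_by_module[name]),
        )

    edges = [
        ModuleEdge(str(r.source).strip(), str(r.target).strip(), str(r.sign).strip())
        for r in edg.itertuples(index=False)
    ]
    provenance = f"membership={Path(membership_path).name} edges={Path(edges_path).name}"
    return SignalingNetwork(modules=modules, edges=edges, provenance=provenance)


def _read_tsv(path: str | Path, required: list[str], allow_empty: bool = False) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        if allow_empty:
            return pd.DataFrame(columns=required)
        raise NetworkFormatError(f"{path}: empty file") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise NetworkFormatError(f"{path}: missing columns {missing}")
    return df[required]


def write_network(
    net: SignalingNetwork, membership_path: str | Path, edges_path: str | Path
) -> None:
    """Serialize a network back to the two-TSV format read by `load_network`."""
    rows = []
    for mod in net.modules.values():
        if mod.genes:
            rows.extend(
                {"gene": g, "module": mod.name, "pathway": mod.pathway, "role": mod.role}
                for g in sorted(mod.genes)
            )
        else:
            rows.append(
                {"gene": "", "module": mod.name, "pathway": mod.pathway, "role": mod.role}
            )
    pd.DataFrame(rows, columns=["gene", "module", "pathway", "role"]).to_csv(
        membership_path, sep="\t", index=False
    )
    pd.DataFrame(
        [{"source": e.source, "target": e.target, "sign": e.sign} for e in net.edges],
        columns=["source", "target", "sign"],
    ).to_csv(edges_path, sep="\t", index=False)


def network_stats(net: SignalingNetwork) -> NetworkStats:
    """Census of a network: distinct genes, modules, edges.

    A gene belonging to two modules is counted once.
    """
    return NetworkStats(
        n_genes=len(net.genes),
        n_modules=len(net.modules),
        n_edges=len(net.edges),
    )


def load_signature_gmt(path: str | Path) -> list[GeneSignature]:
    """Read gene signatures from a GMT file (Broad dialect).

    Each line is ``name<TAB>description<TAB>gene1<TAB>gene2...``; duplicate
    genes within a line are collapsed.
    """
    sigs: list[GeneSignature] = []
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.rstrip("\n\r")
        if not line:
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise NetworkFormatError(
                f"{path}: line {lineno}: GMT line needs name, description and "
                f"at least one gene (got {len(fields)} fields)"
            )
        genes = frozenset(_norm_gene(g) for g in fields[2:] if g.strip())
        if not genes:
            raise NetworkFormatError(f"{path}: line {lineno}: signature with no genes")
        sigs.append(GeneSignature(name=fields[0].strip(), genes=genes))
    return sigs


def signature_network_overlap(
    net: SignalingNetwork, sig: GeneSignature
) -> frozenset[str]:
    """Genes shared between a signature and the network's distinct gene set."""
    return frozenset(net.genes & sig.genes)


def fixture_network() -> SignalingNetwork:
    """The bundled reduced demonstration network (~60 genes, 11 scored modules).

    A small, clearly non-canonical stand-in for a full user-supplied curated
    network; see ``data/fixture_modules.tsv`` for composition notes.
    """
    data_dir = Path(__file__).parent / "data"
    return load_network(data_dir / "fixture_modules.tsv", data_dir / "fixture_edges.tsv")


def role_census(net: SignalingNetwork) -> Mapping[str, int]:
    """Count modules per role (handy for sanity-checking curated inputs)."""
    return dict(Counter(m.role for m in net.modules.values()))
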