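"""Core domain types shared by every stage of the triplet pipeline.

The analysis revolves around three gene roles — IMMUNE, INFLAMMATION and
DISEASE — and triangles in a protein-protein interaction (PPI) graph whose
three genes carry one role each.  Everything downstream (scoring, clustering,
the drug overlay) consumes the in-memory containers defined here; file
parsing lives in :mod:`iimat.data_io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

IMMUNE = "IMMUNE"
INFLAMMATION = "INFLAMMATION"
DISEASE = "DISEASE"
ROLES = (IMMUNE, INFLAMMATION, DISEASE)

CASE = "CASE"
CONTROL = "CONTROL"
GROUPS = (CASE, CONTROL)

#: the seven node categories a gene can occupy once triplet roles are known
ROLE_CATEGORIES = (
    "immune-only",
    "inflammation-only",
    "disease-only",
    "immune&inflammation",
    "disease&immune",
    "disease&inflammation",
    "all-three",
)


def normalize_symbol(symbol: str) -> str:
    """Canonical gene-symbol form: whitespace-stripped, uppercase."""
    return symbol.strip().upper()


def role_category(roles: frozenset[str]) -> str:
    """Map a role set to one of the seven category labels."""
    has = {r: (r in roles) for r in ROLES}
    if all(has.values()):
        return "all-three"
    if has[IMMUNE] and has[INFLAMMATION]:
        return "immune&inflammation"
    if has[DISEASE] and has[IMMUNE]:
        return "disease&immune"
    if has[DISEASE] and has[INFLAMMATION]:
        return "disease&inflammation"
    if has[IMMUNE]:
        return "immune-only"
    if has[INFLAMMATION]:
        return "inflammation-only"
    return "disease-only"


@dataclass(frozen=True)
class GeneRoleCatalog:
    """Map from gene symbol to its non-empty set of roles.

    Symbols are case-normalized; merging catalogs unions role sets per gene,
    which makes the merge commutative and idempotent.
    """

    entries: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for symbol, roles in self.entries.items():
            sym = normalize_symbol(symbol)
            roleset = frozenset(roles)
            if not roleset:
                raise ValueError(f"gene {sym!r} has an empty role set")
            bad = roleset - set(ROLES)
            if bad:
                raise ValueError(f"unknown roles {sorted(bad)} for gene {sym!r}")
            clean[sym] = clean.get(sym, frozenset()) | roleset
        object.__setattr__(self, "entries", clean)

    @classmethod
    def from_symbols(cls, symbols: Iterable[str], role: str) -> "GeneRoleCatalog":
        return cls({s: frozenset({role}) for s in symbols})

    def merge(self, other: "GeneRoleCatalog") -> "GeneRoleCatalog":
        merged: dict[str, frozenset[str]] = dict(self.entries)
        for sym, roles in other.entries.items():
            merged[sym] = merged.get(sym, frozenset()) | roles
        return GeneRoleCatalog(merged)

    def roles_of(self, symbol: str) -> frozenset[str]:
        return self.entries.get(normalize_symbol(symbol), frozenset())

    def genes_with_role(self, role: str) -> set[str]:
        return {g for g, roles in self.entries.items() if role in roles}

    def category_of(self, symbol: str) -> str:
        return role_category(self.roles_of(symbol))

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.entries


@dataclass(frozen=True, order=True)
class Triplet:
    """Three distinct genes forming a PPI triangle, one per role."""

    immune_gene: str
    inflammation_gene: str
    disease_gene: str

    def __post_init__(self) -> None:
        if len({self.immune_gene, self.inflammation_gene, self.disease_gene}) != 3:
            raise ValueError(f"triplet genes must be pairwise distinct: {self}")

    @property
    def genes(self) -> tuple[str, str, str]:
        return (self.immune_gene, self.inflammation_gene, self.disease_gene)

    @property
    def pairs(self) -> tuple[tuple[str, str], tuple[str, str], tuple[str, str]]:
        """The three gene pairs in fixed order: im-in, im-dis, in-dis."""
        return (
            (self.immune_gene, self.inflammation_gene),
            (self.immune_gene, self.disease_gene),
            (self.inflammation_gene, self.disease_gene),
        )

    @property
    def edges(self) -> tuple[frozenset[str], ...]:
        return tuple(frozenset(p) for p in self.pairs)


class ExpressionMatrix:
    """Genes × samples expression values with a binary case/control label.

    Parameters
    ----------
    data:
        DataFrame indexed by gene symbol with one column per sample id.
        Gene symbols must be unique (duplicates are collapsed upstream).
    labels:
        Mapping sample id → ``CASE`` or ``CONTROL``; every column must be
        labeled.
    """

    def __init__(self, data: pd.DataFrame, labels: Mapping[str, str]) -> None:
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene symbols: {dups}")
        labels = {str(s): g for s, g in labels.items()}
        missing = [s for s in data.columns if str(s) not in labels]
        if missing:
            raise ValueError(f"samples without a label: {missing}")
        bad = {g for g in labels.values()} - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        self.data = data.astype(float)
        self.labels = {str(s): labels[str(s)] for s in data.columns}

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples if self.labels[s] == group]

    def group_columns(self, group: str) -> np.ndarray:
        return np.array(
            [i for i, s in enumerate(self.samples) if self.labels[s] == group],
            dtype=int,
        )

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[keep], self.labels)

    def __contains__(self, gene: str) -> bool:
        return gene in self.data.index

    def __repr__(self) -> str:
        n_case = len(self.group_samples(CASE))
        n_ctrl = len(self.group_samples(CONTROL))
        return (
            f"ExpressionMatrix({len(self.genes)} genes, "
            f"{n_case} case / {n_ctrl} control samples)"
        )


@dataclass(frozen=True)
class ProbeAnnotation:
    """Probe id → gene symbols.  A probe may map to several symbols and then
    contributes to each symbol's per-gene mean; probes without a symbol are
    dropped by the reader."""

    mapping: Mapping[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        clean = {
            str(p).strip(): tuple(normalize_symbol(s) for s in syms if s.strip())
            for p, syms in self.mapping.items()
        }
        object.__setattr__(self, "mapping", clean)

    def symbols_for(self, probe: str) -> tuple[str, ...]:
        return self.mapping.get(probe, ())


@dataclass(frozen=True)
class DrugTargetRecord:
    drug_id: str
    drug_name: str
    target: str


@dataclass
class DrugTargetTable:
    """Deduplicated (drug, target-gene) interaction records."""

    records: list[DrugTargetRecord]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        unique: list[DrugTargetRecord] = []
        for rec in self.records:
            key = (rec.drug_id, rec.target)
            if key not in seen:
                seen.add(key)
                unique.append(rec)
        self.records = unique

    def targets_of(self, drug_id: str) -> set[str]:
        return {r.target for r in self.records if r.drug_id == drug_id}

    def drug_names(self) -> dict[str, str]:
        names: dict[str, str] = {}
        for r in self.records:
            names.setdefault(r.drug_id, r.drug_name)
        return names

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class TripletScoreRecord:
    """Per-triplet dysregulation evidence, filled in progressively.

    ``score_dif`` is the product of the three per-gene case/control t-test
    p-values; ``score_pcc`` the absolute product of the three between-group
    Pearson-correlation differences; ``final_score`` the equally weighted
    mean of the two score ranks; ``perm_p`` the permutation p-value of the
    final score.
    """

    triplet: Triplet
    p_immune: float = np.nan
    p_inflammation: float = np.nan
    p_disease: float = np.nan
    pcc_case_im_in: float = np.nan
    pcc_case_im_d: float = np.nan
    pcc_case_in_d: float = np.nan
    pcc_ctrl_im_in: float = np.nan
    pcc_ctrl_im_d: float = np.nan
    pcc_ctrl_in_d: float = np.nan
    score_dif: float = np.nan
    score_pcc: float = np.nan
    rank_dif: float = np.nan
    rank_pcc: float = np.nan
    final_score: float = np.nan
    perm_p: float = np.nan


@dataclass
class TripletNetwork:
    """The union graph of a list of triplets with catalog-derived node roles."""

    triplets: list[Triplet]
    nodes: dict[str, str] = field(default_factory=dict)  # symbol -> category
    edges: set[frozenset[str]] = field(default_factory=set)

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in sorted(self.nodes):
            g.add_node(node, role_category=self.nodes[node])
        for edge in sorted(self.edges, key=lambda e: tuple(sorted(e))):
            u, v = sorted(edge)
            g.add_edge(u, v)
        return g


@dataclass
class TopologyReport:
    degree: dict[str, int]
    slope: float
    r_squared: float


@dataclass
class DysregulatedNetwork(TripletNetwork):
    records: list[TripletScoreRecord] = field(default_factory=list)
    alpha: float = 0.05


@dataclass(frozen=True)
class ClusterRecord:
    members: frozenset[str]
    cohesiveness: float

    @property
    def sorted_members(self) -> tuple[str, ...]:
        return tuple(sorted(self.members))


@dataclass
class ConsensusReport:
    k_values: list[int]
    consensus: dict[int, pd.DataFrame]  # per k: sample × sample matrix
    cdf_area: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int
    assignment: dict[str, int]
    stable: bool


@dataclass
class AssociationResult:
    contingency: pd.DataFrame
    chi2: float
    df: int
    p: float


@dataclass(frozen=True)
class PlantedTruth:
    planted: tuple[Triplet, ...]
    null: tuple[Triplet, ...]

    def __post_init__(self) -> None:
        if set(self.planted) & set(self.null):
            raise ValueError("planted and null triplet lists must be disjoint")
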