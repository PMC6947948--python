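"""Drug-target overlay of the dysregulated triplet network.

Drug nodes are attached to the gene subnetwork wherever a drug targets a
gene that survived dysregulation selection; a drug with no such target is
dropped.  Ranking candidate repurposing drugs by their degree (number of
dysregulated targets) and extracting per-drug subnetworks are the two
read-outs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx

from .types import DrugTargetTable, DysregulatedNetwork, TripletNetwork


@dataclass
class DrugNetwork:
    """Bipartite-ish overlay: gene-gene edges plus drug-gene target edges."""

    gene_nodes: dict[str, str]                 # symbol -> role category
    gene_edges: set[frozenset[str]]
    drug_names: dict[str, str]                 # drug id -> display name
    drug_edges: set[tuple[str, str]] = field(default_factory=set)  # (drug, gene)

    @property
    def n_nodes(self) -> int:
        return len(self.gene_nodes) + len(self.drug_names)

    @property
    def n_edges(self) -> int:
        return len(self.gene_edges) + len(self.drug_edges)

    def targets_of(self, drug_id: str) -> set[str]:
        return {g for d, g in self.drug_edges if d == drug_id}

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in sorted(self.gene_nodes):
            g.add_node(node, node_type="gene",
                       role_category=self.gene_nodes[node])
        for drug in sorted(self.drug_names):
            g.add_node(drug, node_type="drug",
                       drug_name=self.drug_names[drug])
        for edge in sorted(tuple(sorted(e)) for e in self.gene_edges):
            g.add_edge(*edge, interaction="pp")
        for drug, gene in sorted(self.drug_edges):
            g.add_edge(drug, gene, interaction="targets")
        return g


@dataclass(frozen=True)
class DrugDegreeRecord:
    drug_id: str
    drug_name: str
    degree: int
    targets: tuple[str, ...]


def build_drug_network(dys: TripletNetwork | DysregulatedNetwork,
                       drugs: DrugTargetTable) -> DrugNetwork:
    """Join drug-target records onto the gene network.

    The gene side is carried over unchanged; a drug-gene edge is added for
    every (drug, target) record whose target gene is a network node, and
    drugs left without any such edge are dropped.
    """
    gene_nodes = dict(dys.nodes)
    drug_edges: set[tuple[str, str]] = set()
    names: dict[str, str] = {}
    for rec in drugs.records:
        if rec.target in gene_nodes:
            drug_edges.add((rec.drug_id, rec.target))
            names.setdefault(rec.drug_id, rec.drug_name)
    return DrugNetwork(gene_nodes=gene_nodes, gene_edges=set(dys.edges),
                       drug_names=names, drug_edges=drug_edges)


def rank_drugs_by_degree(net: DrugNetwork) -> list[DrugDegreeRecord]:
    """Drugs sorted by number of targeted network genes, descending; ties
    broken lexicographically by drug id."""
    records = []
    for drug_id in net.drug_names:
        targets = tuple(sorted(net.targets_of(drug_id)))
        records.append(DrugDegreeRecord(
            drug_id=drug_id, drug_name=net.drug_names[drug_id],
            degree=len(targets), targets=targets,
        ))
    records.sort(key=lambda r: (-r.degree, r.drug_id))
    return records


def extract_drug_subnetwork(net: DrugNetwork, drug_id: str) -> DrugNetwork:
    """Restrict to one drug, its targets, and the gene edges among those
    targets."""
    if drug_id not in net.drug_names:
        raise KeyError(f"drug {drug_id!r} not in the drug network")
    targets = net.targets_of(drug_id)
    gene_edges = {e for e in net.gene_edges if e <= targets}
    return DrugNetwork(
        gene_nodes={g: c for g, c in net.gene_nodes.items() if g in targets},
        gene_edges=gene_edges,
        drug_names={drug_id: net.drug_names[drug_id]},
        drug_edges={(d, g) for d, g in net.drug_edges if d == drug_id},
    )
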