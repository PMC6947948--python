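"""Triangle enumeration over a role-annotated PPI graph.

A triplet is a triangle whose three genes can be assigned the three roles
immune / inflammation / disease, one role per gene.  Because the genes of a
triangle are distinct by construction, no gene ever fills two role slots;
triangles with no valid assignment are simply not emitted.  A gene carrying
several roles can support several assignments of the same triangle — by
default every valid assignment is emitted as its own triplet (``mode="all"``),
or only the lexicographically first one (``mode="first"``).
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np

from .types import (
    DISEASE,
    GeneRoleCatalog,
    IMMUNE,
    INFLAMMATION,
    TopologyReport,
    Triplet,
    TripletNetwork,
)


def _assignments(genes: tuple[str, str, str],
                 catalog: GeneRoleCatalog) -> list[Triplet]:
    """All valid (immune, inflammation, disease) assignments of a gene triple,
    in lexicographic order of the assigned symbols."""
    out: list[Triplet] = []
    for im in genes:
        if IMMUNE not in catalog.roles_of(im):
            continue
        for inf in genes:
            if inf == im or INFLAMMATION not in catalog.roles_of(inf):
                continue
            (dis,) = (g for g in genes if g not in (im, inf))
            if DISEASE in catalog.roles_of(dis):
                out.append(Triplet(im, inf, dis))
    out.sort()
    return out


def enumerate_iimats(graph: nx.Graph, catalog: GeneRoleCatalog,
                     mode: str = "all") -> list[Triplet]:
    """Enumerate every role-assignable triangle of ``graph``.

    Returns one :class:`Triplet` per valid (gene-set, role-assignment) pair
    (``mode="all"``) or per gene set (``mode="first"``), sorted
    lexicographically by (immune, inflammation, disease) symbol.
    """
    if mode not in ("all", "first"):
        raise ValueError(f"unknown mode {mode!r}")
    triplets: list[Triplet] = []
    nodes = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    for u in nodes:
        # neighbours after u in sorted order: each triangle found exactly once
        later = sorted(n for n in graph[u] if index[n] > index[u])
        for v, w in combinations(later, 2):
            if not graph.has_edge(v, w):
                continue
            assigned = _assignments((u, v, w), catalog)
            if assigned:
                triplets.extend(assigned if mode == "all" else assigned[:1])
    triplets.sort()
    return triplets


def build_triplet_network(triplets: list[Triplet],
                          catalog: GeneRoleCatalog) -> TripletNetwork:
    """Union of all triplet triangles, with catalog-derived node categories.

    The node category comes from the gene's full role set in the catalog,
    not from its per-triplet assignment, so a multifunction gene is labeled
    as such even when every triplet uses only one of its roles.
    """
    edges: set[frozenset[str]] = set()
    nodes: dict[str, str] = {}
    for t in triplets:
        edges.update(t.edges)
        for g in t.genes:
            nodes.setdefault(g, catalog.category_of(g))
    return TripletNetwork(triplets=list(triplets), nodes=nodes, edges=edges)


def role_category_counts(network: TripletNetwork) -> dict[str, int]:
    counts: dict[str, int] = {}
    for category in network.nodes.values():
        counts[category] = counts.get(category, 0) + 1
    return dict(sorted(counts.items()))


def degree_map(network: TripletNetwork) -> dict[str, int]:
    deg = {n: 0 for n in network.nodes}
    for edge in network.edges:
        for n in edge:
            deg[n] += 1
    return deg


def fit_powerlaw(degree_counts: dict[int, int]) -> tuple[float, float]:
    """OLS of log10 n(k) on log10 k over observed degrees k ≥ 1.

    Returns (slope, R²).  Raw frequencies n(k), not probabilities, are
    fitted, matching the usual network-analyzer convention.
    """
    items = sorted((k, n) for k, n in degree_counts.items() if k >= 1 and n > 0)
    if len(items) < 3:
        raise ValueError(
            f"degree-distribution fit needs >=3 distinct degrees, got {len(items)}"
        )
    x = np.log10([k for k, _ in items])
    y = np.log10([n for _, n in items])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return float(slope), float(r2)


def scale_free_fit(network: TripletNetwork) -> TopologyReport:
    """Log-log least-squares fit of the degree frequency distribution.

    For each observed degree k ≥ 1, n(k) is the number of nodes with that
    degree; ordinary least squares on (log10 k, log10 n(k)) yields the slope
    and the coefficient of determination R².  A scale-free network shows an
    approximately linear (negative-slope) relation.
    """
    deg = degree_map(network)
    ks, counts = np.unique([d for d in deg.values() if d >= 1],
                           return_counts=True)
    slope, r2 = fit_powerlaw(dict(zip(ks.tolist(), counts.tolist())))
    return TopologyReport(degree=deg, slope=slope, r_squared=r2)
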