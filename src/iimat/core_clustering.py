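"""Core-cluster extraction and consensus-clustering classification.

Core clusters come from a greedy cohesiveness search in the spirit of
protein-complex detection: the quality of a vertex set S is

    cohesiveness(S) = w_in / (w_in + w_bound + penalty * |S|)

with unit edge weights, where w_in counts edges inside S and w_bound edges
with exactly one endpoint inside.  A local search grows/shrinks S by single
vertex moves from many seeds, overlapping candidates are merged, and the
size/density-filtered survivors are ranked by cohesiveness.

Sample classification uses subsampled k-means consensus clustering: for each
candidate group count k, samples are repeatedly subsampled and k-means
partitions accumulated into a consensus matrix of co-clustering frequencies.
The number of groups is chosen from the relative increase of the area under
the consensus CDF (the classic delta-area elbow), and the final assignment
cuts an average-linkage dendrogram of (1 - consensus) at the chosen k.
"""

from __future__ import annotations

import logging
import warnings
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans
from sklearn.exceptions import ConvergenceWarning

from .types import (
    AssociationResult,
    ClusterRecord,
    ConsensusReport,
    ExpressionMatrix,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# greedy cohesiveness clustering
# ---------------------------------------------------------------------------

def cohesiveness(graph: nx.Graph, subset: Iterable[str],
                 penalty: float = 2.0) -> float:
    """w_in / (w_in + w_bound + penalty * |subset|) with unit edge weights."""
    S = set(subset)
    if not S:
        raise ValueError("cohesiveness of an empty subset is undefined")
    w_in = w_bound = 0
    for u in S:
        for v in graph[u]:
            if v in S:
                w_in += 1  # counted from both endpoints; halved below
            else:
                w_bound += 1
    w_in //= 2
    return w_in / (w_in + w_bound + penalty * len(S))


def _grow_shrink(graph: nx.Graph, seed: Iterable[str],
                 penalty: float) -> frozenset[str]:
    """Local search from a seed set: repeatedly apply the best single-vertex
    addition or removal while it strictly improves cohesiveness."""
    S = set(seed) if isinstance(seed, (set, frozenset, list, tuple)) else {seed}
    score = cohesiveness(graph, S, penalty)
    while True:
        best_score, best_move = score, None
        boundary = sorted({v for u in S for v in graph[u]} - S)
        for v in boundary:
            cand = cohesiveness(graph, S | {v}, penalty)
            if cand > best_score:
                best_score, best_move = cand, ("add", v)
        if len(S) > 1:
            for v in sorted(S):
                cand = cohesiveness(graph, S - {v}, penalty)
                if cand > best_score:
                    best_score, best_move = cand, ("remove", v)
        if best_move is None:
            return frozenset(S)
        action, v = best_move
        (S.add if action == "add" else S.remove)(v)
        score = best_score


def _overlap(a: frozenset[str], b: frozenset[str]) -> float:
    inter = len(a & b)
    return inter * inter / (len(a) * len(b))


def _density(graph: nx.Graph, members: frozenset[str]) -> float:
    n = len(members)
    if n < 2:
        return 0.0
    w_in = sum(1 for u, v in graph.edges(members) if u in members and v in members)
    return w_in / (n * (n - 1) / 2)


def greedy_cohesive_clusters(graph: nx.Graph, penalty: float = 2.0,
                             overlap_merge: float = 0.8, min_size: int = 3,
                             min_density: float = 0.5,
                             top_n: int | None = 4) -> list[ClusterRecord]:
    """Extract up to ``top_n`` core clusters ranked by cohesiveness.

    Seeds every node in decreasing-degree order, runs the grow/shrink local
    search, merges candidate pairs whose overlap score |A∩B|²/(|A||B|)
    reaches ``overlap_merge``, filters by ``min_size`` and induced edge
    density ``min_density``, and returns the best survivors (ties broken by
    lexicographic member list).  ``top_n=None`` returns all survivors.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot cluster an empty graph")
    candidates = best_local_clusters(graph, penalty)
    # iterative pairwise merge of highly overlapping candidates
    merged = True
    while merged:
        merged = False
        out: list[frozenset[str]] = []
        while candidates:
            cur = candidates.pop(0)
            for i, other in enumerate(candidates):
                if _overlap(cur, other) >= overlap_merge:
                    candidates.pop(i)
                    candidates.insert(0, cur | other)
                    merged = True
                    break
            else:
                out.append(cur)
        candidates = out
    survivors = [
        ClusterRecord(members=c, cohesiveness=cohesiveness(graph, c, penalty))
        for c in candidates
        if len(c) >= min_size and _density(graph, c) >= min_density
    ]
    survivors.sort(key=lambda r: (-r.cohesiveness, r.sorted_members))
    return survivors if top_n is None else survivors[:top_n]


def best_local_clusters(graph: nx.Graph,
                        penalty: float = 2.0) -> list[frozenset[str]]:
    """Raw grow/shrink candidates (pre merge/filter).

    Seeds the local search from every vertex in decreasing-degree order,
    from every closed neighborhood, and from every connected component, so
    that optima larger than a vertex's immediate surroundings are also
    reachable; duplicates are dropped, order of first discovery kept.
    """
    nodes = sorted(graph.nodes, key=lambda n: (-graph.degree[n], n))
    seeds: list[Iterable[str]] = list(nodes)
    seeds += [set(graph[v]) | {v} for v in nodes]
    seeds += [comp for comp in nx.connected_components(graph)]
    out: list[frozenset[str]] = []
    seen: set[frozenset[str]] = set()
    for seed in seeds:
        c = _grow_shrink(graph, seed, penalty)
        if c not in seen:
            seen.add(c)
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# consensus clustering of samples
# ---------------------------------------------------------------------------

def _ecdf_area(values: np.ndarray, grid_points: int = 201) -> float:
    """Trapezoid area under the empirical CDF of consensus values on [0,1]."""
    grid = np.linspace(0.0, 1.0, grid_points)
    F = np.searchsorted(np.sort(values), grid, side="right") / len(values)
    return float(np.trapezoid(F, grid))


def delta_areas(cdf_area: Mapping[int, float]) -> dict[int, float]:
    """Relative CDF-area increases: delta(2) = area(2), then
    delta(k) = (area(k) - area(k-1)) / area(k-1)."""
    ks = sorted(cdf_area)
    out = {ks[0]: cdf_area[ks[0]]}
    for prev, k in zip(ks, ks[1:]):
        p = cdf_area[prev]
        out[k] = (cdf_area[k] - p) / p if p > 0 else 0.0
    return out


def choose_k(cdf_area: Mapping[int, float],
             elbow_threshold: float = 0.1) -> int:
    """Largest k whose relative delta-area still reaches the elbow threshold
    (falling back to the smallest tested k when none does)."""
    delta = delta_areas(cdf_area)
    qualifying = [k for k, d in delta.items() if d >= elbow_threshold]
    return max(qualifying) if qualifying else min(cdf_area)


def consensus_cluster(expr_subset: ExpressionMatrix, k_max: int = 4,
                      n_resamples: int = 100, subsample_frac: float = 0.8,
                      seed: int | None = None,
                      elbow_threshold: float = 0.1) -> ConsensusReport:
    """Subsampled k-means consensus clustering of the samples.

    For each k in 2..k_max the samples (profiles over the cluster's genes)
    are subsampled ``n_resamples`` times at ``subsample_frac`` and k-means
    partitions accumulated into a consensus matrix M(i,j) = co-clustered /
    co-sampled.  chosen_k is the largest k whose relative delta-area of the
    consensus CDF is at least ``elbow_threshold``.  The ``stable`` flag
    reports whether the chosen consensus matrix is essentially binary
    (entries within 0.1 of 0 or 1), which fails for structureless data.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    samples = expr_subset.samples
    n = len(samples)
    if n < k_max + 1:
        raise ValueError(f"{n} samples cannot support k_max={k_max}")
    if len(expr_subset.genes) < 1:
        raise ValueError("no genes in the expression subset")
    X = expr_subset.values.T  # samples × genes
    m = max(k_max, int(np.ceil(subsample_frac * n)))
    root = np.random.SeedSequence(0 if seed is None else seed)

    k_values = list(range(2, k_max + 1))
    consensus: dict[int, pd.DataFrame] = {}
    cdf_area: dict[int, float] = {}
    for k in k_values:
        co = np.zeros((n, n))
        together = np.zeros((n, n))
        for r in range(n_resamples):
            ss = np.random.SeedSequence(root.entropy, spawn_key=(k, r))
            rng = np.random.default_rng(ss)
            idx = np.sort(rng.choice(n, size=m, replace=False))
            km_seed = int(ss.generate_state(1)[0] % (2**31))
            with warnings.catch_warnings():
                # k-means may find < k clusters on degenerate (duplicate)
                # profiles; that case is surfaced via the stability flag
                warnings.simplefilter("ignore", ConvergenceWarning)
                labels = KMeans(n_clusters=k, n_init=10,
                                random_state=km_seed).fit_predict(X[idx])
            same = labels[:, None] == labels[None, :]
            together[np.ix_(idx, idx)] += 1
            co[np.ix_(idx, idx)] += same
        with np.errstate(invalid="ignore"):
            M = np.where(together > 0, co / np.maximum(together, 1), 0.0)
        M = (M + M.T) / 2.0
        np.fill_diagonal(M, 1.0)
        consensus[k] = pd.DataFrame(M, index=samples, columns=samples)
        iu = np.triu_indices(n, k=1)
        cdf_area[k] = _ecdf_area(M[iu])

    delta_area = delta_areas(cdf_area)
    chosen_k = choose_k(cdf_area, elbow_threshold)

    M = consensus[chosen_k].to_numpy()
    dist = 1.0 - M
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    flat = fcluster(Z, t=chosen_k, criterion="maxclust")
    assignment = {s: int(g) for s, g in zip(samples, flat)}

    # stable = essentially binary consensus that genuinely separates the
    # samples into chosen_k groups; all-ones matrices (e.g. identical
    # samples, where k-means collapses) are degenerate, not stable
    iu = np.triu_indices(n, k=1)
    vals = M[iu]
    stable = bool(
        np.mean((vals <= 0.1) | (vals >= 0.9)) >= 0.9
        and (vals <= 0.1).any()
        and len(set(assignment.values())) == chosen_k
    )
    if not stable:
        log.warning("consensus clustering at k=%d is unstable or degenerate",
                    chosen_k)
    return ConsensusReport(
        k_values=k_values, consensus=consensus, cdf_area=cdf_area,
        delta_area=delta_area, chosen_k=chosen_k, assignment=assignment,
        stable=stable,
    )


# ---------------------------------------------------------------------------
# cluster vs disease-status association
# ---------------------------------------------------------------------------

def cluster_disease_association(assignment: Mapping[str, int],
                                labels: Mapping[str, str]
                                ) -> AssociationResult:
    """Pearson chi-square (no continuity correction) on the consensus-group ×
    disease-status contingency table.  Groups or statuses with zero samples
    are dropped with a warning; a table smaller than 2×2 is degenerate."""
    samples = sorted(assignment)
    missing = [s for s in samples if s not in labels]
    if missing:
        raise ValueError(f"samples without a disease label: {missing}")
    table = pd.crosstab(
        pd.Series({s: assignment[s] for s in samples}, name="group"),
        pd.Series({s: labels[s] for s in samples}, name="status"),
    )
    empty_rows = table.index[(table.sum(axis=1) == 0)]
    if len(empty_rows):
        log.warning("dropping empty groups %s", list(empty_rows))
        table = table.drop(index=empty_rows)
    if table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(
            f"degenerate contingency table {table.shape}: chi-square undefined"
        )
    chi2, p, df, _ = stats.chi2_contingency(table.to_numpy(), correction=False)
    return AssociationResult(contingency=table, chi2=float(chi2),
                             df=int(df), p=float(p))
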