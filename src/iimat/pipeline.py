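"""End-to-end orchestration: simulate/load → network → scoring → clusters →
drugs, with a machine-readable run report.

A single global seed fans out to per-stage deterministic substreams
(``SeedSequence(seed, spawn_key=(stage,))``), so toggling one stage off does
not perturb another stage's randomness, and re-running with the same config
and seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import data_io
from .core_clustering import (
    cluster_disease_association,
    consensus_cluster,
    greedy_cohesive_clusters,
)
from .drug_overlay import build_drug_network, rank_drugs_by_degree
from .dysregulation_scoring import (
    permutation_pvalues,
    rank_concordance,
    select_dysregulated,
)
from .synthetic_data import Scenario, SimulationConfig, simulate_scenario
from .triplet_network import (
    build_triplet_network,
    enumerate_iimats,
    role_category_counts,
    scale_free_fit,
)
from .types import GeneRoleCatalog, Triplet, TripletScoreRecord

log = logging.getLogger(__name__)

_STAGES = ("simulate", "build_net", "score", "clusters", "drugs")
_STAGE_SEED_KEY = {name: i for i, name in enumerate(_STAGES)}


@dataclass
class RunConfig:
    """All pipeline inputs and stage parameters in one place."""

    outdir: str = "iimat_run"
    seed: int = 0
    # inputs (ignored when simulate=True)
    roles_gmt: str | None = None
    ppi: str | None = None
    ppi_dialect: str = "generic-tsv"
    expression: str | None = None
    labels: str | None = None
    probe_map: str | None = None
    series_matrix: bool = False
    drug_targets: str | None = None
    # stage toggles
    simulate: bool = True
    run_build_net: bool = True
    run_score: bool = True
    run_clusters: bool = True
    run_drugs: bool = True
    # stage parameters
    sim: dict[str, Any] = field(default_factory=dict)
    assignment_mode: str = "all"
    n_perm: int = 1000
    alpha: float = 0.05
    test: str = "student"
    penalty: float = 2.0
    overlap_merge: float = 0.8
    min_size: int = 3
    min_density: float = 0.5
    top_n: int = 4
    k_max: int = 4
    n_resamples: int = 100
    subsample_frac: float = 0.8
    elbow_threshold: float = 0.1

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


def _stage_seed(config: RunConfig, stage: str) -> int:
    ss = np.random.SeedSequence(config.seed,
                                spawn_key=(_STAGE_SEED_KEY[stage],))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _count_rows(path: Path) -> int:
    if path.suffix in (".json", ".graphml"):
        return sum(1 for _ in path.read_text().splitlines())
    return sum(1 for line in path.read_text().splitlines() if line.strip())


class RunReport(dict):
    """JSON-serialisable report: parameters, per-stage counts, file manifest."""

    def add_file(self, stage: str, path: Path) -> None:
        self.setdefault("manifest", {})[str(path.name)] = {
            "stage": stage,
            "rows": _count_rows(path),
            "sha256": _sha256(path),
        }

    def save(self, path: Path) -> None:
        path.write_text(json.dumps(self, indent=2, sort_keys=True) + "\n")


def _require(config: RunConfig, stage: str, **paths: str | None) -> None:
    for name, p in paths.items():
        if p is None:
            raise FileNotFoundError(
                f"stage {stage!r}: required input {name!r} not configured")
        if not Path(p).exists():
            raise FileNotFoundError(
                f"stage {stage!r}: input {name!r} missing at {p}")


def _write_scored(records: list[TripletScoreRecord], path: Path) -> None:
    cols = ("immune_gene", "inflammation_gene", "disease_gene",
            "p_immune", "p_inflammation", "p_disease",
            "score_dif", "score_pcc", "rank_dif", "rank_pcc",
            "final_score", "perm_p")
    lines = ["\t".join(cols)]
    for r in records:
        lines.append("\t".join([
            r.triplet.immune_gene, r.triplet.inflammation_gene,
            r.triplet.disease_gene,
            *(f"{v:.10g}" for v in (
                r.p_immune, r.p_inflammation, r.p_disease,
                r.score_dif, r.score_pcc, r.rank_dif, r.rank_pcc,
                r.final_score, r.perm_p))
        ]))
    path.write_text("\n".join(lines) + "\n")


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured stages in order and write a run report.

    Stage order: simulate (or load) → build-net → score/permute/select →
    clusters → drugs.  Every output file enters the manifest with its row
    count and SHA-256, and the report itself is written as
    ``run_report.json`` in the output directory.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(parameters=config.to_dict(), seed=config.seed,
                       stages={})

    scenario: Scenario | None = None
    if config.simulate:
        sim_cfg = SimulationConfig(**{"seed": _stage_seed(config, "simulate"),
                                      **config.sim})
        scenario = simulate_scenario(sim_cfg)
        indir = outdir / "inputs"
        indir.mkdir(exist_ok=True)
        data_io.write_gene_roles_gmt(scenario.catalog, indir / "roles.gmt")
        data_io.write_ppi_edges(scenario.graph, indir / "ppi.tsv")
        data_io.write_expression(scenario.expression, indir / "expression.tsv")
        data_io.write_labels(scenario.expression.labels, indir / "labels.tsv")
        data_io.write_drug_targets(scenario.drugs, indir / "drug_targets.tsv")
        truth = {
            "planted": [list(t.genes) for t in scenario.truth.planted],
            "null": [list(t.genes) for t in scenario.truth.null],
        }
        (indir / "truth.json").write_text(
            json.dumps(truth, indent=2, sort_keys=True) + "\n")
        for f in sorted(indir.iterdir()):
            report.add_file("simulate", f)
        config = dataclasses.replace(
            config,
            roles_gmt=str(indir / "roles.gmt"), ppi=str(indir / "ppi.tsv"),
            expression=str(indir / "expression.tsv"),
            labels=str(indir / "labels.tsv"),
            drug_targets=str(indir / "drug_targets.tsv"),
        )
        report["stages"]["simulate"] = {
            "n_genes": scenario.graph.number_of_nodes(),
            "n_edges": scenario.graph.number_of_edges(),
            "n_planted": len(scenario.truth.planted),
            "n_null": len(scenario.truth.null),
        }

    catalog: GeneRoleCatalog | None = None
    triplets: list[Triplet] = []
    if config.run_build_net:
        _require(config, "build_net", roles_gmt=config.roles_gmt,
                 ppi=config.ppi)
        catalog = data_io.read_gene_roles(config.roles_gmt, fmt="gmt")
        graph = data_io.read_ppi_edges(config.ppi, config.ppi_dialect)
        triplets = enumerate_iimats(graph, catalog, mode=config.assignment_mode)
        network = build_triplet_network(triplets, catalog)
        data_io.write_triplets(triplets, outdir / "triplets.tsv")
        data_io.write_sif(network.to_graph(), outdir / "iimat_network.sif")
        data_io.write_graphml(network.to_graph(),
                              outdir / "iimat_network.graphml")
        topo: dict[str, Any] = {"role_categories": role_category_counts(network)}
        try:
            fit = scale_free_fit(network)
            topo.update(slope=fit.slope, r_squared=fit.r_squared,
                        max_degree=max(fit.degree.values(), default=0))
        except ValueError as exc:
            topo.update(degree_fit_error=str(exc))
        (outdir / "topology.json").write_text(
            json.dumps(topo, indent=2, sort_keys=True) + "\n")
        for name in ("triplets.tsv", "iimat_network.sif",
                     "iimat_network.graphml", "topology.json"):
            report.add_file("build_net", outdir / name)
        report["stages"]["build_net"] = {
            "n_triplets": len(triplets),
            "n_nodes": len(network.nodes),
            "n_edges": len(network.edges),
        }

    records: list[TripletScoreRecord] = []
    dys = None
    if config.run_score:
        _require(config, "score", expression=config.expression,
                 labels=config.labels)
        if not triplets:
            raise RuntimeError("score stage needs build_net output")
        expr = data_io.load_expression(
            config.expression, config.labels, config.probe_map,
            series_matrix=config.series_matrix)
        records = permutation_pvalues(
            expr, triplets, n_perm=config.n_perm,
            seed=_stage_seed(config, "score"), test=config.test)
        dys = select_dysregulated(records, catalog, alpha=config.alpha)
        _write_scored(records, outdir / "scored_triplets.tsv")
        data_io.write_sif(dys.to_graph(), outdir / "dysregulated_network.sif")
        data_io.write_graphml(dys.to_graph(),
                              outdir / "dysregulated_network.graphml")
        for name in ("scored_triplets.tsv", "dysregulated_network.sif",
                     "dysregulated_network.graphml"):
            report.add_file("score", outdir / name)
        stage: dict[str, Any] = {
            "n_scored": len(records),
            "n_significant": len(dys.records),
            "alpha": config.alpha,
            "n_perm": config.n_perm,
        }
        if dys.records:
            stage["rank_concordance_pct"] = rank_concordance(records,
                                                             dys.records)
        report["stages"]["score"] = stage

    if config.run_clusters:
        if dys is None:
            raise RuntimeError("clusters stage needs score output")
        stage = {"clusters": []}
        if dys.edges:
            clusters = greedy_cohesive_clusters(
                dys.to_graph(), penalty=config.penalty,
                overlap_merge=config.overlap_merge, min_size=config.min_size,
                min_density=config.min_density, top_n=config.top_n)
            lines = ["cluster\tcohesiveness\tmembers"]
            for i, c in enumerate(clusters, 1):
                lines.append(f"C{i}\t{c.cohesiveness:.10g}\t"
                             + ",".join(c.sorted_members))
            (outdir / "clusters.tsv").write_text("\n".join(lines) + "\n")
            report.add_file("clusters", outdir / "clusters.tsv")
            stage["clusters"] = [
                {"members": list(c.sorted_members),
                 "cohesiveness": c.cohesiveness} for c in clusters]
            if clusters:
                expr = data_io.load_expression(
                    config.expression, config.labels, config.probe_map,
                    series_matrix=config.series_matrix)
                sub = expr.subset_genes(clusters[0].sorted_members)
                try:
                    rep = consensus_cluster(
                        sub, k_max=config.k_max,
                        n_resamples=config.n_resamples,
                        subsample_frac=config.subsample_frac,
                        seed=_stage_seed(config, "clusters"),
                        elbow_threshold=config.elbow_threshold)
                except ValueError as exc:
                    stage["consensus_error"] = str(exc)
                else:
                    cons = {
                        "k_values": rep.k_values,
                        "cdf_area": {str(k): v for k, v in rep.cdf_area.items()},
                        "delta_area": {str(k): v
                                       for k, v in rep.delta_area.items()},
                        "chosen_k": rep.chosen_k,
                        "stable": rep.stable,
                        "assignment": rep.assignment,
                    }
                    (outdir / "consensus_report.json").write_text(
                        json.dumps(cons, indent=2, sort_keys=True) + "\n")
                    report.add_file("clusters", outdir / "consensus_report.json")
                    for k, M in rep.consensus.items():
                        p = outdir / f"consensus_k{k}.tsv"
                        M.to_csv(p, sep="\t", float_format="%.10g")
                        report.add_file("clusters", p)
                    stage["chosen_k"] = rep.chosen_k
                    try:
                        assoc = cluster_disease_association(
                            rep.assignment, expr.labels)
                        stage["chi2"] = assoc.chi2
                        stage["chi2_df"] = assoc.df
                        stage["chi2_p"] = assoc.p
                    except ValueError as exc:
                        stage["chi2_error"] = str(exc)
        report["stages"]["clusters"] = stage

    if config.run_drugs:
        if dys is None:
            raise RuntimeError("drugs stage needs score output")
        _require(config, "drugs", drug_targets=config.drug_targets)
        drugs = data_io.read_drug_targets(config.drug_targets)
        net = build_drug_network(dys, drugs)
        ranking = rank_drugs_by_degree(net)
        lines = ["drug_id\tdrug_name\tdegree\ttargets"]
        for r in ranking:
            lines.append(f"{r.drug_id}\t{r.drug_name}\t{r.degree}\t"
                         + ",".join(r.targets))
        (outdir / "drug_rank.tsv").write_text("\n".join(lines) + "\n")
        data_io.write_sif(net.to_graph(), outdir / "drug_network.sif")
        data_io.write_graphml(net.to_graph(), outdir / "drug_network.graphml")
        for name in ("drug_rank.tsv", "drug_network.sif",
                     "drug_network.graphml"):
            report.add_file("drugs", outdir / name)
        report["stages"]["drugs"] = {
            "n_drugs": len(net.drug_names),
            "n_nodes": net.n_nodes,
            "n_edges": net.n_edges,
            "top_degree": ranking[0].degree if ranking else 0,
        }

    report.save(outdir / "run_report.json")
    return report
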