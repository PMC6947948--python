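"""Readers and writers for the pipeline's external file formats.

All formats are plain text: one-symbol-per-line or GMT role lists, two-column
(or HPRD flat-file) PPI edge lists, TSV expression matrices (optionally in GEO
series-matrix layout), probe→symbol maps, sample label tables and drug-target
tables.  Everything downstream consumes only the in-memory types from
:mod:`iimat.types`.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .types import (
    CASE,
    CONTROL,
    DrugTargetRecord,
    DrugTargetTable,
    ExpressionMatrix,
    GeneRoleCatalog,
    ProbeAnnotation,
    ROLES,
    Triplet,
    normalize_symbol,
)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# gene role catalogs
# ---------------------------------------------------------------------------

def read_gene_roles(path: str | Path, role: str | None = None,
                    fmt: str = "auto") -> GeneRoleCatalog:
    """Read a role catalog fragment from a symbol list or a GMT file.

    Parameters
    ----------
    path:
        One-gene-per-line text/TSV (requires ``role``) or a GMT file whose
        set names are the roles (``role`` ignored).
    role:
        Role label to tag every symbol with, for the plain-list format.
    fmt:
        ``"list"``, ``"gmt"`` or ``"auto"`` (by ``.gmt`` extension).
    """
    path = Path(path)
    if fmt == "auto":
        fmt = "gmt" if path.suffix.lower() == ".gmt" else "list"
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"empty gene role file: {path}")
    if fmt == "gmt":
        return _read_roles_gmt(text, path)
    if role is None:
        raise ValueError("a role label is required for one-gene-per-line files")
    if role not in ROLES:
        raise ValueError(f"unknown role {role!r}; expected one of {ROLES}")
    symbols: list[str] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        fields = [f for f in line.strip().split("\t") if f]
        if not fields:
            continue
        if len(fields) > 1:
            log.warning("%s:%d: malformed line (multiple fields), skipped",
                        path, lineno)
            continue
        symbols.append(normalize_symbol(fields[0]))
    return GeneRoleCatalog.from_symbols(symbols, role)


def _read_roles_gmt(text: str, path: Path) -> GeneRoleCatalog:
    catalog = GeneRoleCatalog({})
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            log.warning("%s:%d: malformed GMT line, skipped", path, lineno)
            continue
        set_role = fields[0].strip().upper()
        if set_role not in ROLES:
            log.warning("%s:%d: GMT set %r is not a known role, skipped",
                        path, lineno, fields[0])
            continue
        symbols = [normalize_symbol(s) for s in fields[2:] if s.strip()]
        catalog = catalog.merge(GeneRoleCatalog.from_symbols(symbols, set_role))
    return catalog


def merge_catalogs(*fragments: GeneRoleCatalog) -> GeneRoleCatalog:
    """Union role sets per gene across fragments (commutative, idempotent)."""
    merged = GeneRoleCatalog({})
    for frag in fragments:
        merged = merged.merge(frag)
    return merged


def write_gene_roles_gmt(catalog: GeneRoleCatalog, path: str | Path) -> None:
    lines = []
    for role in ROLES:
        genes = sorted(catalog.genes_with_role(role))
        lines.append("\t".join([role, f"{role.lower()} gene set", *genes]))
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# PPI edge lists
# ---------------------------------------------------------------------------

#: symbol column positions of the HPRD binary-interaction flat file
_HPRD_SYMBOL_COLS = (0, 3)


def read_ppi_edges(path: str | Path, dialect: str = "generic-tsv") -> nx.Graph:
    """Read an undirected simple PPI graph from a tab-separated edge list.

    ``generic-tsv`` takes the first two columns as interactor symbols;
    ``hprd-flat`` uses the HPRD flat-file layout (symbols in columns 1 and 4).
    Self-loops and duplicate (including reversed) pairs are dropped and the
    counts logged.
    """
    path = Path(path)
    if dialect == "generic-tsv":
        cols = (0, 1)
    elif dialect == "hprd-flat":
        cols = _HPRD_SYMBOL_COLS
    else:
        raise ValueError(f"unknown PPI dialect {dialect!r}")
    graph = nx.Graph()
    n_self = n_dup = 0
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) == 1:  # tolerate space-separated two-column files
            fields = line.split()
        if len(fields) <= max(cols):
            log.warning("%s: short line skipped: %r", path, line)
            continue
        u = normalize_symbol(fields[cols[0]])
        v = normalize_symbol(fields[cols[1]])
        if not u or not v:
            continue
        if u == v:
            n_self += 1
            continue
        if graph.has_edge(u, v):
            n_dup += 1
            continue
        graph.add_edge(u, v)
    if n_self or n_dup:
        log.info("%s: dropped %d self-loops and %d duplicate pairs",
                 path, n_self, n_dup)
    return graph


def write_ppi_edges(graph: nx.Graph, path: str | Path) -> None:
    lines = [f"{u}\t{v}" for u, v in sorted(tuple(sorted(e)) for e in graph.edges)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a TSV matrix: first column row ids (probes or genes), remaining
    columns one per sample."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = [str(c).strip() for c in df.columns]
    return df


def read_series_matrix(path: str | Path) -> pd.DataFrame:
    """Read the data block of a GEO series-matrix file.

    Metadata lines start with ``!``; the expression table sits between the
    ``!series_matrix_table_begin`` and ``!series_matrix_table_end`` markers.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, l in enumerate(lines)
                     if l.startswith("!series_matrix_table_begin"))
        end = next(i for i, l in enumerate(lines)
                   if l.startswith("!series_matrix_table_end"))
    except StopIteration as exc:
        raise ValueError(f"{path}: missing series-matrix table markers") from exc
    body = "\n".join(lines[start + 1:end])
    from io import StringIO
    df = pd.read_csv(StringIO(body), sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip().str.strip('"')
    df.columns = [str(c).strip().strip('"') for c in df.columns]
    return df


def read_probe_map(path: str | Path) -> ProbeAnnotation:
    """Read probe<TAB>symbol; multi-symbol probes may list symbols separated
    by ``///`` (Affymetrix convention) or commas.  Probes with no symbol are
    dropped."""
    mapping: dict[str, tuple[str, ...]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        probe = fields[0].strip()
        if not probe:
            continue
        raw = fields[1] if len(fields) > 1 else ""
        symbols = tuple(
            normalize_symbol(s)
            for part in raw.split("///")
            for s in part.split(",")
            if s.strip()
        )
        if symbols:
            mapping[probe] = symbols
    return ProbeAnnotation(mapping)


def read_labels(path: str | Path) -> dict[str, str]:
    """Read sample<TAB>{case,control} labels (case-insensitive)."""
    labels: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}: malformed label line: {line!r}")
        group = fields[1].strip().upper()
        if group not in (CASE, CONTROL):
            raise ValueError(f"{path}: unknown group {fields[1]!r}")
        labels[fields[0].strip()] = group
    return labels


def write_labels(labels: Mapping[str, str], path: str | Path) -> None:
    lines = [f"{s}\t{g.lower()}" for s, g in labels.items()]
    Path(path).write_text("\n".join(lines) + "\n")


def collapse_probes(raw: pd.DataFrame, annotation: ProbeAnnotation,
                    labels: Mapping[str, str]) -> ExpressionMatrix:
    """Collapse a probe × sample matrix to gene level by averaging.

    Each gene's row is the arithmetic mean over all probes annotated to it;
    probes without a symbol are dropped, and a probe annotated to several
    symbols contributes to each of them.
    """
    gene_probes: dict[str, list[str]] = {}
    for probe in raw.index:
        for sym in annotation.symbols_for(str(probe)):
            gene_probes.setdefault(sym, []).append(str(probe))
    if not gene_probes:
        raise ValueError("no probe maps to a gene symbol")
    rows = {
        gene: raw.loc[probes].mean(axis=0)
        for gene, probes in sorted(gene_probes.items())
    }
    data = pd.DataFrame(rows).T
    data.index.name = "gene"
    return ExpressionMatrix(data, labels)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene")


def load_expression(matrix_path: str | Path, labels_path: str | Path,
                    probe_map_path: str | Path | None = None,
                    series_matrix: bool = False) -> ExpressionMatrix:
    """Convenience loader: matrix (+ optional probe map) + labels → matrix.

    Without a probe map, row ids are taken to be gene symbols already;
    duplicate symbol rows are averaged the same way probes are.
    """
    reader = read_series_matrix if series_matrix else read_expression_tsv
    raw = reader(matrix_path)
    labels = read_labels(labels_path)
    labels = {s: g for s, g in labels.items() if s in set(map(str, raw.columns))}
    if probe_map_path is not None:
        return collapse_probes(raw, read_probe_map(probe_map_path), labels)
    ann = ProbeAnnotation({str(r): (normalize_symbol(str(r)),) for r in raw.index})
    return collapse_probes(raw, ann, labels)


# ---------------------------------------------------------------------------
# drug-target tables
# ---------------------------------------------------------------------------

_DRUG_COLUMNS = ("drug_id", "drug_name", "gene_symbol")


def read_drug_targets(path: str | Path) -> DrugTargetTable:
    """Read a TSV drug-target table with drug_id / drug_name / gene_symbol
    columns; rows with an empty symbol are skipped with a warning."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = [c for c in _DRUG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records: list[DrugTargetRecord] = []
    for _, row in df.iterrows():
        target = normalize_symbol(row["gene_symbol"])
        if not target:
            log.warning("%s: drug %s row with empty gene symbol skipped",
                        path, row["drug_id"])
            continue
        records.append(
            DrugTargetRecord(row["drug_id"].strip(), row["drug_name"].strip(),
                             target)
        )
    return DrugTargetTable(records)


def write_drug_targets(table: DrugTargetTable, path: str | Path) -> None:
    lines = ["\t".join(_DRUG_COLUMNS)]
    lines += [f"{r.drug_id}\t{r.drug_name}\t{r.target}" for r in table.records]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# triplet tables and network exports
# ---------------------------------------------------------------------------

def write_triplets(triplets: Iterable[Triplet], path: str | Path) -> None:
    lines = ["immune_gene\tinflammation_gene\tdisease_gene"]
    lines += [f"{t.immune_gene}\t{t.inflammation_gene}\t{t.disease_gene}"
              for t in triplets]
    Path(path).write_text("\n".join(lines) + "\n")


def read_triplets(path: str | Path) -> list[Triplet]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return [
        Triplet(row["immune_gene"], row["inflammation_gene"], row["disease_gene"])
        for _, row in df.iterrows()
    ]


def write_sif(graph: nx.Graph, path: str | Path,
              interaction: str = "pp") -> None:
    """Cytoscape SIF export; per-edge ``interaction`` attribute wins over the
    default relation type."""
    lines = []
    for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
        rel = graph.edges[u, v].get("interaction", interaction)
        lines.append(f"{u}\t{rel}\t{v}")
    for node in sorted(graph.nodes):
        if graph.degree[node] == 0:
            lines.append(str(node))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_graphml(graph: nx.Graph, path: str | Path) -> None:
    # rebuild in sorted order so exports are byte-stable across runs
    ordered = nx.Graph()
    for node in sorted(graph.nodes):
        ordered.add_node(node, **graph.nodes[node])
    for u, v in sorted(tuple(sorted(e)) for e in graph.edges):
        ordered.add_edge(u, v, **graph.edges[u, v])
    nx.write_graphml(ordered, str(path))
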