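"""Delimited-table IO for protease-web datasets and graph serialization.

Table dialects
--------------
protein table (TSV): accession, gene_name, merops_id, catalytic_class,
    inhibitor_classes (semicolon-joined), trap_inhibitor (0/1)
cleavage table (TSV): protease_acc, substrate_acc, physiological_relevance,
    source
inhibition table (TSV): inhibitor_acc, protease_acc

Graph formats: GraphML and GML (node role/class attributes and the edge
``kind`` attribute preserved) and a canonical edge-list TSV sorted
lexicographically so exports diff bit-exactly.
"""

from __future__ import annotations

import logging
from pathlib import Path

import networkx as nx
import pandas as pd

from .graph import ProteaseWebGraph
from .records import (
    CleavageRecord,
    InhibitionRecord,
    ProteinRecord,
    ValidationError,
)

__all__ = ["load_tables", "records_from_frames", "write_tables",
           "export_graph", "import_graph"]

logger = logging.getLogger(__name__)

PROTEIN_COLUMNS = ["accession", "gene_name", "merops_id", "catalytic_class",
                   "inhibitor_classes", "trap_inhibitor"]
CLEAVAGE_COLUMNS = ["protease_acc", "substrate_acc",
                    "physiological_relevance", "source"]
INHIBITION_COLUMNS = ["inhibitor_acc", "protease_acc"]


class TableParseError(ValueError):
    """A required column is missing or a table cannot be parsed."""


def _read_tsv(path, required: list[str], label: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.ParserError as exc:  # pragma: no cover - passthrough
        raise TableParseError(f"{label} table {path}: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TableParseError(
            f"{label} table {path}: missing required column(s) "
            f"{', '.join(missing)}")
    return df


def _protein_from_row(row: pd.Series) -> ProteinRecord:
    roles = set()
    merops = row["merops_id"] or None
    cat = row["catalytic_class"] or "none"
    inh_classes = frozenset(
        c for c in str(row["inhibitor_classes"]).split(";") if c)
    if cat != "none":
        roles.add("protease")
    if inh_classes:
        roles.add("inhibitor")
    if not roles:
        roles.add("substrate_only")
    return ProteinRecord(
        accession=row["accession"],
        gene_name=row["gene_name"],
        merops_id=merops,
        roles=frozenset(roles),
        catalytic_class=cat,
        inhibitor_classes=inh_classes,
        trap_inhibitor=bool(int(row["trap_inhibitor"] or 0)),
    )


def load_tables(
    protein_table,
    cleavage_table,
    inhibition_table,
    strict: bool = True,
) -> tuple[list[ProteinRecord], list[CleavageRecord], list[InhibitionRecord]]:
    """Parse the three dataset tables into validated records.

    In strict mode (default) an edge row referencing an unknown accession
    raises; in lenient mode such rows are dropped with a logged warning.
    Duplicate protein accessions always raise.
    """
    pdf = _read_tsv(protein_table, PROTEIN_COLUMNS, "protein")
    cdf = _read_tsv(cleavage_table, CLEAVAGE_COLUMNS, "cleavage")
    idf = _read_tsv(inhibition_table, INHIBITION_COLUMNS, "inhibition")

    proteins: list[ProteinRecord] = []
    seen: set[str] = set()
    for _, row in pdf.iterrows():
        rec = _protein_from_row(row)
        if rec.accession in seen:
            raise ValidationError(f"duplicate accession {rec.accession!r}")
        seen.add(rec.accession)
        proteins.append(rec)

    cleavages: list[CleavageRecord] = []
    dropped = 0
    for i, row in cdf.iterrows():
        if row["protease_acc"] not in seen or row["substrate_acc"] not in seen:
            if strict:
                raise ValidationError(
                    f"cleavage row {i}: unknown accession in "
                    f"{row['protease_acc']!r} -> {row['substrate_acc']!r}")
            dropped += 1
            continue
        cleavages.append(CleavageRecord(
            protease_acc=row["protease_acc"],
            substrate_acc=row["substrate_acc"],
            physiological_relevance=row["physiological_relevance"] or "unknown",
            source=row["source"],
        ))
    inhibitions: list[InhibitionRecord] = []
    for i, row in idf.iterrows():
        if row["inhibitor_acc"] not in seen or row["protease_acc"] not in seen:
            if strict:
                raise ValidationError(
                    f"inhibition row {i}: unknown accession in "
                    f"{row['inhibitor_acc']!r} -> {row['protease_acc']!r}")
            dropped += 1
            continue
        inhibitions.append(InhibitionRecord(
            inhibitor_acc=row["inhibitor_acc"],
            protease_acc=row["protease_acc"],
        ))
    if dropped:
        logger.warning("dropped %d edge rows referencing unknown accessions",
                       dropped)
    return proteins, cleavages, inhibitions


def records_from_frames(
    proteins_df: pd.DataFrame,
    cleavages_df: pd.DataFrame,
    inhibitions_df: pd.DataFrame,
) -> tuple[list[ProteinRecord], list[CleavageRecord], list[InhibitionRecord]]:
    """In-memory counterpart of :func:`load_tables` (strict mode)."""
    proteins = [_protein_from_row(row.astype(str))
                for _, row in proteins_df.iterrows()]
    cleavages = [
        CleavageRecord(
            protease_acc=row["protease_acc"],
            substrate_acc=row["substrate_acc"],
            physiological_relevance=row["physiological_relevance"],
            source=str(row.get("source", "")),
        )
        for _, row in cleavages_df.iterrows()
    ]
    inhibitions = [
        InhibitionRecord(inhibitor_acc=row["inhibitor_acc"],
                         protease_acc=row["protease_acc"])
        for _, row in inhibitions_df.iterrows()
    ]
    return proteins, cleavages, inhibitions


def write_tables(proteins_df: pd.DataFrame, cleavages_df: pd.DataFrame,
                 inhibitions_df: pd.DataFrame, out_dir) -> dict[str, Path]:
    """Write the three tables to ``out_dir`` in the canonical TSV dialect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "proteins": out_dir / "proteins.tsv",
        "cleavages": out_dir / "cleavages.tsv",
        "inhibitions": out_dir / "inhibitions.tsv",
    }
    proteins_df.to_csv(paths["proteins"], sep="\t", index=False)
    cleavages_df.to_csv(paths["cleavages"], sep="\t", index=False)
    inhibitions_df.to_csv(paths["inhibitions"], sep="\t", index=False)
    return paths


# -- graph serialization -------------------------------------------------

_FORMATS = ("graphml", "gml", "tsv")


def export_graph(web: ProteaseWebGraph, path, fmt: str = "graphml") -> None:
    """Serialize a graph with node attributes and edge kinds.

    The TSV dialect is a header line ``source\\ttarget\\tkind`` followed by
    one edge per line, sorted lexicographically; the provenance label is a
    ``#provenance:`` comment after the header.
    """
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown graph format {fmt!r}; use one of {_FORMATS}")
    path = Path(path)
    if fmt == "tsv":
        lines = ["source\ttarget\tkind",
                 f"#provenance:{web.provenance}"]
        lines += sorted(f"{u}\t{v}\t{k}" for u, v, k in web.g.edges(keys=True))
        lines += sorted(f"{n}\t\tnode" for n in nx.isolates(web.g))
        path.write_text("\n".join(lines) + "\n")
        return
    g = web.g.copy()
    g.graph["provenance"] = web.provenance
    if fmt == "graphml":
        nx.write_graphml(g, path)
    else:
        nx.write_gml(g, path)


def import_graph(path, fmt: str = "graphml") -> ProteaseWebGraph:
    """Read a graph written by :func:`export_graph`."""
    fmt = fmt.lower()
    if fmt not in _FORMATS:
        raise ValueError(f"unknown graph format {fmt!r}; use one of {_FORMATS}")
    path = Path(path)
    if fmt == "tsv":
        g = nx.MultiDiGraph()
        provenance = "imported"
        lines = path.read_text().splitlines()
        if not lines or lines[0].split("\t") != ["source", "target", "kind"]:
            raise TableParseError(f"{path}:1: bad edge-list header")
        for lineno, line in enumerate(lines[1:], start=2):
            if line.startswith("#provenance:"):
                provenance = line.split(":", 1)[1]
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise TableParseError(
                    f"{path}:{lineno}: expected 3 tab-separated fields")
            u, v, k = parts
            if k == "node" and not v:
                g.add_node(u)
            else:
                g.add_edge(u, v, key=k, kind=k)
        return ProteaseWebGraph(g, provenance)
    if fmt == "graphml":
        g = nx.read_graphml(path, force_multigraph=True)
    else:
        g = nx.read_gml(path)
        if not g.is_multigraph():  # GML of a multigraph reads back as multi
            g = nx.MultiDiGraph(g)
    # restore kind-valued edge keys (GraphML/GML use integer keys)
    h = nx.MultiDiGraph()
    h.add_nodes_from(g.nodes(data=True))
    for u, v, data in g.edges(data=True):
        kind = data.get("kind", "arc")
        h.add_edge(u, v, key=kind, **data)
    provenance = g.graph.get("provenance", "imported")
    return ProteaseWebGraph(h, provenance)
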