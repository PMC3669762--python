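"""Sequence and table I/O.

Reads scaffold FASTA files into :class:`ScaffoldRecord` collections, joins
tab-delimited annotation tables onto them, and writes tables and
co-clustering support networks (SIF and GraphML).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "ScaffoldRecord",
    "AnnotationTable",
    "read_fasta",
    "write_fasta",
    "read_annotation",
    "annotate_records",
    "write_table",
    "write_graph",
    "read_graph",
]

# IUPAC nucleotide codes (uppercase); '-' tolerated for gapped scaffolds.
IUPAC_CHARS = frozenset("ACGTURYSWKMBDHVN-")


@dataclass(frozen=True)
class ScaffoldRecord:
    """One assembled sequence with optional site/taxon/coverage metadata."""

    id: str
    sequence: str
    site: str | None = None
    taxon: str | None = None
    coverage: float | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("scaffold id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"scaffold {self.id!r}: sequence must be non-empty")
        if self.coverage is not None and self.coverage < 0:
            raise ValueError(
                f"scaffold {self.id!r}: coverage must be >= 0, got {self.coverage}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class AnnotationTable:
    """Per-scaffold metadata keyed by scaffold id.

    ``rows`` maps scaffold id to a dict with optional keys
    ``site``, ``taxon`` and ``coverage``.
    """

    rows: dict[str, dict] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.rows)

    def __contains__(self, scaffold_id: str) -> bool:
        return scaffold_id in self.rows

    def get(self, scaffold_id: str) -> dict | None:
        return self.rows.get(scaffold_id)


def _check_sequence(seq: str, record_id: str) -> None:
    bad = set(seq) - IUPAC_CHARS
    if bad:
        pos = next(i for i, c in enumerate(seq) if c in bad)
        raise ValueError(
            f"record {record_id!r}: non-IUPAC character {seq[pos]!r} "
            f"at position {pos}"
        )


def read_fasta(path: str | Path) -> list[ScaffoldRecord]:
    """Parse a FASTA file into an ordered list of scaffold records.

    Ids are the first whitespace-delimited token of the header; sequences
    are uppercased. Duplicate ids, non-IUPAC characters and empty files
    raise ``ValueError``.
    """
    path = Path(path)
    records: list[ScaffoldRecord] = []
    seen: set[str] = set()
    current_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        nonlocal current_id, chunks
        if current_id is None:
            return
        seq = "".join(chunks).upper()
        _check_sequence(seq, current_id)
        records.append(ScaffoldRecord(id=current_id, sequence=seq))
        current_id, chunks = None, []

    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                rid = line[1:].split()[0] if line[1:].split() else ""
                if not rid:
                    raise ValueError(f"{path}: empty FASTA header")
                if rid in seen:
                    raise ValueError(f"{path}: duplicate scaffold id {rid!r}")
                seen.add(rid)
                current_id = rid
            else:
                if current_id is None:
                    raise ValueError(f"{path}: sequence data before first header")
                chunks.append(line.strip())
    flush()
    if not records:
        raise ValueError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[ScaffoldRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_ID_COLUMN_ALIASES = ("scaffold", "scaffold_id", "id")


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read a tab-delimited annotation table (scaffold id, site, taxon, coverage).

    The header row names the columns; the scaffold-id column is mandatory
    (accepted names: ``scaffold``, ``scaffold_id``, ``id``). Missing
    optional columns yield absent fields. '#'-prefixed lines are ignored.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    cols = {c.lower(): c for c in df.columns}
    id_col = next((cols[a] for a in _ID_COLUMN_ALIASES if a in cols), None)
    if id_col is None:
        raise ValueError(
            f"{path}: no scaffold-id column (expected one of "
            f"{_ID_COLUMN_ALIASES}); found columns {list(df.columns)}"
        )
    table = AnnotationTable()
    for _, row in df.iterrows():
        sid = row[id_col]
        if pd.isna(sid) or not str(sid):
            raise ValueError(f"{path}: row with empty scaffold id")
        sid = str(sid)
        if sid in table.rows:
            raise ValueError(f"{path}: duplicated scaffold id {sid!r}")
        entry: dict = {}
        for key in ("site", "taxon"):
            if key in cols and not pd.isna(row[cols[key]]):
                entry[key] = str(row[cols[key]])
        if "coverage" in cols and not pd.isna(row[cols["coverage"]]):
            cov = float(row[cols["coverage"]])
            if cov < 0:
                raise ValueError(f"{path}: negative coverage for {sid!r}")
            entry["coverage"] = cov
        table.rows[sid] = entry
    return table


def annotate_records(
    records: Sequence[ScaffoldRecord], table: AnnotationTable
) -> tuple[list[ScaffoldRecord], list[str]]:
    """Join annotations onto records.

    Returns annotated records (order preserved) plus the list of table ids
    that matched no record — unmatched ids are reported, never dropped
    silently.
    """
    out = []
    matched: set[str] = set()
    for rec in records:
        entry = table.get(rec.id)
        if entry is None:
            out.append(rec)
        else:
            matched.add(rec.id)
            out.append(replace(rec, **entry))
    unmatched = [sid for sid in table.rows if sid not in matched]
    return out, unmatched


def write_table(rows: Iterable[Mapping], path: str | Path, sep: str = "\t") -> None:
    """Write an iterable of mappings as a delimited table with a header row."""
    rows = list(rows)
    path = Path(path)
    with path.open("w", newline="") as fh:
        if not rows:
            return
        writer = csv.DictWriter(fh, fieldnames=list(rows[0].keys()), delimiter=sep)
        writer.writeheader()
        writer.writerows(rows)


def write_graph(
    edges: Iterable[tuple[str, str, float]],
    path: str | Path,
    format: str = "sif",
    nodes: Iterable[str] | None = None,
) -> None:
    """Write a support network as SIF (``a pp b``) or GraphML.

    GraphML stores the support weight as numeric edge attribute
    ``support``; SIF discards weights (Cytoscape dialect).
    """
    path = Path(path)
    fmt = format.lower()
    edge_list = list(edges)
    for a, b, s in edge_list:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"edge ({a},{b}): support {s} outside [0,1]")
    if fmt == "sif":
        with path.open("w") as fh:
            for a, b, _ in edge_list:
                fh.write(f"{a}\tpp\t{b}\n")
    elif fmt == "graphml":
        g = nx.Graph()
        if nodes is not None:
            g.add_nodes_from(nodes)
        for a, b, s in edge_list:
            g.add_edge(a, b, support=float(s))
        nx.write_graphml(g, path)
    else:
        raise ValueError(f"unknown graph format {format!r} (use 'sif' or 'graphml')")


def read_graph(path: str | Path, format: str = "graphml") -> set[tuple[str, str, float]]:
    """Read a network back as a set of ``(a, b, support)`` edges (a < b)."""
    path = Path(path)
    fmt = format.lower()
    edges: set[tuple[str, str, float]] = set()
    if fmt == "graphml":
        g = nx.read_graphml(path)
        for a, b, data in g.edges(data=True):
            a, b = sorted((str(a), str(b)))
            edges.add((a, b, float(data.get("support", 1.0))))
    elif fmt == "sif":
        with path.open() as fh:
            for line in fh:
                parts = line.split()
                if len(parts) >= 3:
                    a, b = sorted((parts[0], parts[2]))
                    edges.add((a, b, 1.0))
    else:
        raise ValueError(f"unknown graph format {format!r}")
    return edges
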