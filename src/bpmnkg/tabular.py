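"""Tabular BPMN process descriptions: parsing, extraction, linting.

The input dialect is a four-column table — ID, ACTION, Type, TARGET — in
which every row declares one BPMN element (its identifier, human-readable
action label and BBO class) together with at most one outgoing link.  An
element with several outgoing links (a gateway fan-out) is written either as
repeated rows sharing ID/ACTION/Type, or as a single row whose TARGET cell
holds a semicolon-separated list; both spellings are accepted and normalize
to the same rows.

Extraction splits a parsed table into a node collection (one record per
distinct identifier, first-appearance order) and a sequence collection (one
directed source→target record per non-empty TARGET, duplicates merged).
"""

from __future__ import annotations

import csv
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from .bbo import BboClass, Vocabulary, builtin_vocabulary
from .errors import ConflictError, SchemaError, VocabularyError
from .report import Severity, ValidationReport

REQUIRED_COLUMNS = ("ID", "ACTION", "TYPE", "TARGET")


@dataclass(frozen=True)
class RawRow:
    """One table row: element identifier, action label, class IRI, target."""

    element_id: str
    action_label: str
    bbo_class_iri: str
    target_id: str


@dataclass
class ProcessTable:
    process_name: str
    rows: list[RawRow] = field(default_factory=list)
    source_path: str = "inline"

    def __len__(self) -> int:
        return len(self.rows)

    def __iter__(self) -> Iterator[RawRow]:
        return iter(self.rows)


@dataclass(frozen=True)
class NodeRecord:
    element_id: str
    action_label: str
    bbo_class: BboClass


@dataclass(frozen=True)
class SequenceRecord:
    source_id: str
    target_id: str


class NodeCollection:
    """Ordered, duplicate-free set of nodes keyed by element identifier."""

    def __init__(self, records: Iterable[NodeRecord] = ()):
        self._records: dict[str, NodeRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: NodeRecord) -> None:
        if record.element_id in self._records:
            existing = self._records[record.element_id]
            if existing != record:
                raise ConflictError(
                    f"element {record.element_id!r} redefined: "
                    f"{existing.action_label!r}/{existing.bbo_class.local_name} vs "
                    f"{record.action_label!r}/{record.bbo_class.local_name}"
                )
            return
        self._records[record.element_id] = record

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[NodeRecord]:
        return iter(self._records.values())

    def __contains__(self, element_id: str) -> bool:
        return element_id in self._records

    def __getitem__(self, element_id: str) -> NodeRecord:
        return self._records[element_id]

    def ids(self) -> list[str]:
        return list(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NodeCollection):
            return NotImplemented
        return list(self) == list(other)


class SequenceCollection:
    """Ordered collection of directed links; identical pairs are merged."""

    def __init__(self, records: Iterable[SequenceRecord] = ()):
        self._records: dict[tuple[str, str], SequenceRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, record: SequenceRecord) -> None:
        if not record.source_id or not record.target_id:
            raise ValueError("sequence endpoints must be non-empty")
        self._records.setdefault((record.source_id, record.target_id), record)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self._records.values())

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self._records

    def pairs(self) -> list[tuple[str, str]]:
        return list(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SequenceCollection):
            return NotImplemented
        return list(self) == list(other)


def _normalize_header(fields: list[str]) -> dict[str, int]:
    mapping: dict[str, int] = {}
    for idx, name in enumerate(fields):
        key = (name or "").strip().upper()
        if key in REQUIRED_COLUMNS and key not in mapping:
            mapping[key] = idx
    missing = [c for c in REQUIRED_COLUMNS if c not in mapping]
    if missing:
        raise SchemaError(
            "missing required column(s): " + ", ".join(missing)
            + " (header must contain ID, ACTION, Type, TARGET)"
        )
    return mapping


def _rows_from_cells(
    cell_rows: Iterable[list[str]], source: str
) -> list[RawRow]:
    it = iter(cell_rows)
    try:
        header = next(it)
    except StopIteration:
        raise SchemaError(f"{source}: empty file, no header row")
    columns = _normalize_header(header)
    rows: list[RawRow] = []
    seen_pairs: set[tuple[str, str]] = set()
    for lineno, cells in enumerate(it, start=2):
        if not any((c or "").strip() for c in cells):
            continue  # blank line

        def cell(col: str) -> str:
            idx = columns[col]
            return (cells[idx] if idx < len(cells) else "").strip()

        element_id = cell("ID")
        if not element_id:
            raise SchemaError(f"{source}:{lineno}: empty ID cell")
        if any(ch.isspace() for ch in element_id):
            raise SchemaError(
                f"{source}:{lineno}: ID {element_id!r} contains whitespace"
            )
        action = cell("ACTION")
        class_iri = cell("TYPE")
        raw_target = cell("TARGET")
        # semicolon-delimited TARGET lists expand to repeated rows
        targets = [t.strip() for t in raw_target.split(";")] if raw_target else [""]
        for target in targets:
            if target == "" and len(targets) > 1:
                continue
            pair = (element_id, target)
            if target and pair in seen_pairs:
                warnings.warn(
                    f"{source}:{lineno}: duplicate link {element_id} -> {target}; "
                    "deduplicated",
                    stacklevel=2,
                )
                continue
            seen_pairs.add(pair)
            rows.append(RawRow(element_id, action, class_iri, target))
    return rows


def _infer_dialect(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".xlsx", ".xlsm"):
        return "xlsx"
    if suffix in (".tsv", ".tab"):
        return "tsv"
    return "csv"


def read_table(
    path: str | Path,
    dialect: str | None = None,
    process_name: str | None = None,
) -> ProcessTable:
    """Read a CSV/TSV/XLSX process table in the ID/ACTION/Type/TARGET dialect.

    Header matching is case-insensitive and order-free; cells are trimmed of
    surrounding whitespace; an empty TARGET is preserved as empty (the row
    declares a node with no outgoing link).  Duplicate (ID, TARGET) pairs are
    deduplicated with a warning.

    Raises ``FileNotFoundError`` for a missing file and :class:`SchemaError`
    for a missing required column or an empty/whitespace ID.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    dialect = (dialect or _infer_dialect(path)).lower()
    if dialect == "xlsx":
        from openpyxl import load_workbook

        book = load_workbook(path, read_only=True, data_only=True)
        sheet = book.worksheets[0]
        cell_rows = [
            ["" if v is None else str(v) for v in row]
            for row in sheet.iter_rows(values_only=True)
        ]
        book.close()
    elif dialect in ("csv", "tsv"):
        delim = "\t" if dialect == "tsv" else ","
        with open(path, newline="", encoding="utf-8") as fh:
            cell_rows = list(csv.reader(fh, delimiter=delim))
    else:
        raise ValueError(f"unknown dialect {dialect!r} (expected csv, tsv or xlsx)")
    rows = _rows_from_cells(cell_rows, str(path))
    return ProcessTable(
        process_name=process_name or path.stem,
        rows=rows,
        source_path=str(path),
    )


def read_table_string(
    text: str, process_name: str = "inline", delimiter: str = ","
) -> ProcessTable:
    """Parse delimited table text held in memory (same dialect as files)."""
    cell_rows = list(csv.reader(io.StringIO(text), delimiter=delimiter))
    return ProcessTable(process_name, _rows_from_cells(cell_rows, "inline"), "inline")


def write_table(table: ProcessTable, path: str | Path, dialect: str = "csv") -> None:
    """Write a table back out in the same four-column dialect."""
    path = Path(path)
    delim = "\t" if dialect.lower() == "tsv" else ","
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delim)
        writer.writerow(["ID", "ACTION", "Type", "TARGET"])
        for row in table.rows:
            writer.writerow(
                [row.element_id, row.action_label, row.bbo_class_iri, row.target_id]
            )


def extract(
    table: ProcessTable, vocabulary: Vocabulary | None = None
) -> tuple[NodeCollection, SequenceCollection]:
    """Split a table into node and sequence collections.

    One node per distinct element identifier (the first occurrence defines
    the label and class; a later occurrence with a conflicting label or class
    raises :class:`ConflictError`); one sequence per row with a non-empty
    TARGET, identical pairs merged.  Order is first-appearance order.
    """
    vocab = vocabulary or builtin_vocabulary()
    nodes = NodeCollection()
    sequences = SequenceCollection()
    for row in table.rows:
        cls = vocab.resolve_class(row.bbo_class_iri)
        nodes.add(NodeRecord(row.element_id, row.action_label, cls))
        if row.target_id:
            sequences.add(SequenceRecord(row.element_id, row.target_id))
    return nodes, sequences


def rebuild_table(
    nodes: NodeCollection,
    sequences: SequenceCollection,
    process_name: str = "rebuilt",
) -> ProcessTable:
    """Inverse of :func:`extract`: emit one row per outgoing link (or per
    link-less node), preserving node order.  ``extract`` over the result
    reproduces the input collections exactly."""
    outgoing: dict[str, list[str]] = {n.element_id: [] for n in nodes}
    for seq in sequences:
        outgoing.setdefault(seq.source_id, []).append(seq.target_id)
    rows: list[RawRow] = []
    for node in nodes:
        targets = outgoing.get(node.element_id) or [""]
        for target in targets:
            rows.append(
                RawRow(node.element_id, node.action_label, node.bbo_class.iri, target)
            )
    return ProcessTable(process_name, rows, "inline")


_STRUCTURAL_OK_WITHOUT_LABEL = ("SequenceFlow", "Gateway")


def lint_table(
    table: ProcessTable,
    strict: bool = False,
    vocabulary: Vocabulary | None = None,
) -> ValidationReport:
    """Report structural problems in a table before encoding.

    Findings: unknown class IRIs (error), dangling targets (warning, or
    error under ``strict``), orphan nodes with no link at all (warning),
    self-loops (warning), and unlabeled rows for classes that normally carry
    an action label (warning).
    """
    vocab = vocabulary or builtin_vocabulary()
    report = ValidationReport()
    defined: dict[str, RawRow] = {}
    for row in table.rows:
        defined.setdefault(row.element_id, row)

    degree: dict[str, int] = {eid: 0 for eid in defined}
    seen_dangling: set[str] = set()
    for row in table.rows:
        try:
            cls = vocab.resolve_class(row.bbo_class_iri)
        except VocabularyError:
            report.add(
                Severity.ERROR,
                "unknown-class",
                row.element_id,
                f"class term {row.bbo_class_iri!r} is not in the vocabulary",
            )
            cls = None
        if row.target_id:
            degree[row.element_id] += 1
            if row.target_id in degree:
                degree[row.target_id] += 1
            if row.target_id == row.element_id:
                report.add(
                    Severity.WARNING,
                    "self-loop",
                    row.element_id,
                    "row links an element to itself",
                )
            elif row.target_id not in defined and row.target_id not in seen_dangling:
                seen_dangling.add(row.target_id)
                report.add(
                    Severity.ERROR if strict else Severity.WARNING,
                    "dangling-target",
                    row.target_id,
                    f"target {row.target_id!r} has no defining row",
                )
        if (
            cls is not None
            and not row.action_label
            and cls.local_name not in _STRUCTURAL_OK_WITHOUT_LABEL
        ):
            report.add(
                Severity.WARNING,
                "empty-action",
                row.element_id,
                f"{cls.local_name} row has an empty ACTION label",
            )

    no_orphan_check = {"Process", "StartEvent", "EndEvent"}
    for eid, row in defined.items():
        try:
            cls_name = vocab.resolve_class(row.bbo_class_iri).local_name
        except VocabularyError:
            continue
        if degree[eid] == 0 and cls_name not in no_orphan_check:
            report.add(
                Severity.WARNING,
                "orphan-node",
                eid,
                f"{cls_name} element has no incoming or outgoing link",
            )
    return report
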