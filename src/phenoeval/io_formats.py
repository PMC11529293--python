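"""Readers and writers for definitions, LLM responses, dictionaries, reports.

Two reading paths exist on purpose.  :func:`read_definition_table` is strict:
it serves curated reference files, where a missing column or an unparseable
token is a data error worth failing on.  :func:`parse_llm_table` is tolerant:
model responses wrap tables in prose, improvise dialects, and garble rows, so
it extracts the first well-formed table region it can find, skips rows it
cannot parse, and reports everything it skipped in a diagnostics record
instead of raising — output inconsistency is a finding to measure, not a
crash.

Three table dialects are supported, covering the styles LLMs actually emit:
markdown pipe tables, comma/tab-delimited rows, and whitespace-aligned
columns.  Detection prefers pipe tables, then delimited, then aligned.
"""

from __future__ import annotations

import csv
import enum
import io
import json
import re
from dataclasses import dataclass, field
from typing import TextIO

import pandas as pd
from pydantic import BaseModel, Field

from .defmodel import (
    CodeCount,
    DefinitionRow,
    DictionaryLoadError,
    LogicLabel,
    MalformedCodeError,
    PhenotypeDefinition,
    RowParseError,
    SchemaError,
    VocabularyDictionary,
    VocabularyId,
    _squash,
    normalize_code,
)
from .mapping import CrossMap
from .metrics import METRIC_FIELDS, MetricReport, ReportDocument

__all__ = [
    "TableDialect",
    "ParseDiagnostics",
    "ParseResult",
    "read_definition_table",
    "write_definition_table",
    "parse_llm_table",
    "load_vocabulary",
    "load_crossmap",
    "write_report",
    "read_report",
    "ReportDocument",
    "CANONICAL_HEADER",
]


class TableDialect(enum.Enum):
    """Supported table renderings for definition files and LLM responses."""

    DELIMITED = "delimited"
    MARKDOWN_PIPE = "markdown-pipe"
    ALIGNED_WHITESPACE = "aligned-whitespace"


#: Canonical column header used by all writers.
CANONICAL_HEADER = ("Logic", "Vocabulary", "Concept code", "Concept name", "Code count")

#: Header-cell synonyms (squashed form -> logical field).
_HEADER_SYNONYMS: dict[str, str] = {
    "logic": "logic",
    "vocabulary": "vocabulary",
    "vocab": "vocabulary",
    "codevocabulary": "vocabulary",
    "conceptvocabulary": "vocabulary",
    "codesystem": "vocabulary",
    "code": "code",
    "conceptcode": "code",
    "codeidentifier": "code",
    "codeid": "code",
    "conceptid": "code",
    "identifier": "code",
    "name": "name",
    "conceptname": "name",
    "codename": "name",
    "string": "name",
    "description": "name",
    "count": "count",
    "codecount": "count",
    "codescount": "count",
}

_FIELDS = ("logic", "vocabulary", "code", "name", "count")
_FIELD_TO_CANONICAL = dict(zip(_FIELDS, CANONICAL_HEADER))

_PIPE_SEPARATOR_CELL = re.compile(r"^:?-{2,}:?$")
_MULTISPACE = re.compile(r"\s{2,}")


def _read_text(source: str | TextIO) -> str:
    return source.read() if hasattr(source, "read") else source


# ---------------------------------------------------------------------------
# Cell extraction per dialect
# ---------------------------------------------------------------------------

def _pipe_cells(line: str) -> list[str]:
    stripped = line.strip()
    if stripped.startswith("|"):
        stripped = stripped[1:]
    if stripped.endswith("|"):
        stripped = stripped[:-1]
    return [c.strip() for c in stripped.split("|")]


def _is_pipe_separator(cells: list[str]) -> bool:
    return bool(cells) and all(_PIPE_SEPARATOR_CELL.fullmatch(c) for c in cells if c) and any(cells)


def _delimited_cells(line: str, delimiter: str) -> list[str]:
    try:
        parsed = next(csv.reader(io.StringIO(line), delimiter=delimiter), [])
    except csv.Error:
        parsed = line.split(delimiter)
    return [c.strip() for c in parsed]


def _aligned_cells(line: str) -> list[str]:
    return [c.strip() for c in _MULTISPACE.split(line.strip()) if c.strip()]


def _extract_cells(lines: list[str], dialect: TableDialect, delimiter: str = ",") -> list[list[str]]:
    rows: list[list[str]] = []
    for line in lines:
        if not line.strip():
            continue
        if dialect is TableDialect.MARKDOWN_PIPE:
            cells = _pipe_cells(line)
            if _is_pipe_separator(cells):
                continue
        elif dialect is TableDialect.DELIMITED:
            cells = _delimited_cells(line, delimiter)
        else:
            cells = _aligned_cells(line)
        rows.append(cells)
    return rows


# ---------------------------------------------------------------------------
# Dialect detection
# ---------------------------------------------------------------------------

def detect_dialect(text: str) -> TableDialect:
    """Deterministic dialect detection: pipe, then delimited, then aligned."""
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if any(ln.count("|") >= 2 for ln in lines):
        return TableDialect.MARKDOWN_PIPE
    if any("\t" in ln for ln in lines) or any(ln.count(",") >= 1 for ln in lines):
        return TableDialect.DELIMITED
    return TableDialect.ALIGNED_WHITESPACE


def _delimiter_for(text: str) -> str:
    return "\t" if "\t" in text else ","


# ---------------------------------------------------------------------------
# Strict reference reader
# ---------------------------------------------------------------------------

def _map_header(cells: list[str]) -> dict[str, int]:
    """Map logical fields to column indices via the synonym table."""
    mapping: dict[str, int] = {}
    for i, cell in enumerate(cells):
        field_name = _HEADER_SYNONYMS.get(_squash(cell))
        if field_name is not None and field_name not in mapping:
            mapping[field_name] = i
    return mapping


def _build_row(cells: list[str], columns: dict[str, int]) -> DefinitionRow:
    """Build a DefinitionRow from cells; raises ValueError family on bad tokens."""
    needed = max(columns.values())
    if len(cells) <= needed:
        raise ValueError(f"expected at least {needed + 1} cells, got {len(cells)}")
    logic = LogicLabel.parse(cells[columns["logic"]])
    count = CodeCount.parse(cells[columns["count"]])
    vocab = VocabularyId.resolve(cells[columns["vocabulary"]])
    code = cells[columns["code"]].strip()
    name = cells[columns["name"]].strip()
    if not code:
        raise MalformedCodeError("empty code")
    if not name:
        raise ValueError("empty name")
    return DefinitionRow(logic=logic, vocabulary=vocab, code=code, name=name, count=count)


def read_definition_table(
    source: str | TextIO,
    dialect: TableDialect | None = None,
    *,
    phenotype_name: str = "",
    source_kind: str = "reference",
    provenance: str = "",
) -> PhenotypeDefinition:
    """Read a curated definition table (header row required); strict.

    Header tokens are matched case-insensitively through a synonym table
    ("Concept code" == "Code identifier", "Concept name" == "Code name").
    A missing mandatory column raises :class:`SchemaError` naming the column;
    an unparseable logic or count token raises :class:`RowParseError` with the
    0-based data-row index.
    """
    text = _read_text(source)
    d = dialect or detect_dialect(text)
    rows_cells = _extract_cells(text.splitlines(), d, _delimiter_for(text))
    if not rows_cells:
        raise SchemaError("input contains no table rows (header required)")

    columns = _map_header(rows_cells[0])
    missing = [f for f in _FIELDS if f not in columns]
    if missing:
        names = ", ".join(f"'{_FIELD_TO_CANONICAL[f]}'" for f in missing)
        raise SchemaError(f"missing mandatory column(s): {names}")

    rows: list[DefinitionRow] = []
    for i, cells in enumerate(rows_cells[1:]):
        try:
            rows.append(_build_row(cells, columns))
        except (ValueError, MalformedCodeError) as exc:
            raise RowParseError(i, str(exc)) from exc
    return PhenotypeDefinition(
        phenotype_name=phenotype_name,
        rows=tuple(rows),
        source=source_kind,
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

def _row_cells(row: DefinitionRow) -> list[str]:
    return [
        row.logic.render(),
        row.vocabulary.canonical,
        row.code,
        row.name,
        row.count.render(),
    ]


def write_definition_table(
    defn: PhenotypeDefinition, dialect: TableDialect = TableDialect.DELIMITED
) -> str:
    """Render a definition in the requested dialect, canonical header included."""
    header = list(CANONICAL_HEADER)
    body = [_row_cells(r) for r in defn.rows]
    if dialect is TableDialect.DELIMITED:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(header)
        writer.writerows(body)
        return buf.getvalue()
    if dialect is TableDialect.MARKDOWN_PIPE:
        def render(cells: list[str]) -> str:
            return "| " + " | ".join(cells) + " |"

        lines = [render(header), render(["---"] * len(header))]
        lines.extend(render(cells) for cells in body)
        return "\n".join(lines) + "\n"
    # aligned whitespace: pad columns to their maximum width, two-space gutter
    table = [header] + body
    widths = [max(len(row[i]) for row in table) for i in range(len(header))]
    lines = [
        "  ".join(cell.ljust(w) for cell, w in zip(row, widths)).rstrip()
        for row in table
    ]
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Tolerant LLM-response parser
# ---------------------------------------------------------------------------

@dataclass
class ParseDiagnostics:
    """Everything the tolerant parser had to skip or decide."""

    no_table: bool = False
    extra_tables: int = 0
    skipped_rows: list[tuple[int, str]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


@dataclass
class ParseResult:
    definition: PhenotypeDefinition
    diagnostics: ParseDiagnostics


def _find_regions(lines: list[str]) -> tuple[list[tuple[int, int]], TableDialect | None, str]:
    """Locate contiguous table-like line regions; first dialect that yields any wins.

    Returns (regions as [start, end) line spans, dialect, delimiter).
    """

    def runs(predicate) -> list[tuple[int, int]]:
        found: list[tuple[int, int]] = []
        start = None
        for i, line in enumerate(lines):
            if line.strip() and predicate(line):
                if start is None:
                    start = i
            else:
                if start is not None and i - start >= 2:
                    found.append((start, i))
                start = None
        if start is not None and len(lines) - start >= 2:
            found.append((start, len(lines)))
        return found

    pipe = runs(lambda ln: ln.count("|") >= 2)
    if pipe:
        return pipe, TableDialect.MARKDOWN_PIPE, ","
    tab = runs(lambda ln: "\t" in ln)
    if tab:
        return tab, TableDialect.DELIMITED, "\t"
    comma = runs(lambda ln: len(_delimited_cells(ln, ",")) >= 3)
    # require some internal consistency so comma-rich prose is not a "table"
    comma = [
        (s, e)
        for s, e in comma
        if len({len(_delimited_cells(ln, ",")) for ln in lines[s:e] if ln.strip()}) <= 2
    ]
    if comma:
        return comma, TableDialect.DELIMITED, ","
    aligned = runs(lambda ln: len(_aligned_cells(ln)) >= 3)
    if aligned:
        return aligned, TableDialect.ALIGNED_WHITESPACE, ","
    return [], None, ","


def parse_llm_table(
    text: str,
    *,
    phenotype_name: str = "",
    provenance: str = "",
) -> ParseResult:
    """Extract a candidate definition from free-form LLM response text.

    The first well-formed table region wins; prose before and after is
    ignored, additional table regions are counted in the diagnostics.  Rows
    that fail cell-count or logic/count parsing are skipped and recorded.
    When no table region exists the result is an empty candidate with a
    ``no_table`` diagnostic — never an exception, whatever the input.
    """
    diagnostics = ParseDiagnostics()
    empty = PhenotypeDefinition(
        phenotype_name=phenotype_name, rows=(), source="candidate", provenance=provenance
    )
    try:
        lines = text.splitlines()
        regions, dialect, delimiter = _find_regions(lines)
        if not regions or dialect is None:
            diagnostics.no_table = True
            return ParseResult(empty, diagnostics)
        if len(regions) > 1:
            diagnostics.extra_tables = len(regions) - 1
            diagnostics.notes.append(
                f"{len(regions) - 1} additional table region(s) ignored (first table wins)"
            )
        start, end = regions[0]
        rows_cells = _extract_cells(lines[start:end], dialect, delimiter)
        if not rows_cells:
            diagnostics.no_table = True
            return ParseResult(empty, diagnostics)

        columns = _map_header(rows_cells[0])
        if all(f in columns for f in _FIELDS):
            data = rows_cells[1:]
            offset = 1
        else:
            # no recognizable header: assume the canonical five-column order
            columns = dict(zip(_FIELDS, range(5)))
            data = rows_cells
            offset = 0
            diagnostics.notes.append("no header row recognized; positional columns assumed")

        rows: list[DefinitionRow] = []
        for i, cells in enumerate(data):
            if len(cells) <= max(columns.values()):
                diagnostics.skipped_rows.append((i + offset, "cell-count"))
                continue
            try:
                rows.append(_build_row(cells, columns))
            except (ValueError, MalformedCodeError) as exc:
                diagnostics.skipped_rows.append((i + offset, str(exc)))
        if not rows and not data:
            diagnostics.notes.append("table region had a header but no data rows")
        return ParseResult(empty.with_rows(rows), diagnostics)
    except Exception as exc:  # contract: total over arbitrary text
        diagnostics.no_table = True
        diagnostics.notes.append(f"parse-error: {type(exc).__name__}: {exc}")
        return ParseResult(empty, diagnostics)


# ---------------------------------------------------------------------------
# Vocabulary dictionaries and crossmaps
# ---------------------------------------------------------------------------

def load_vocabulary(
    source: str | TextIO,
    vocab: VocabularyId | str,
    code_pattern: str = "",
) -> VocabularyDictionary:
    """Load a two-column code/name table into a vocabulary dictionary.

    Accepts tab- or comma-delimited input, with or without a ``code,name``
    header.  Codes are normalized on load; duplicate normalized codes carrying
    conflicting names abort the load with every collision listed.
    """
    if isinstance(vocab, str):
        vocab = VocabularyId.resolve(vocab)
    text = _read_text(source)
    delimiter = _delimiter_for(text)
    entries: dict[str, str] = {}
    collisions: list[str] = []
    for raw in csv.reader(io.StringIO(text), delimiter=delimiter):
        cells = [c.strip() for c in raw]
        if not any(cells):
            continue
        if len(cells) < 2:
            raise DictionaryLoadError(f"expected 2 columns, got {len(cells)}: {raw!r}")
        code_cell, name = cells[0], cells[1]
        if (_squash(code_cell), _squash(name)) == ("code", "name"):
            continue  # header row
        code = normalize_code(vocab, code_cell)
        existing = entries.get(code)
        if existing is not None and existing != name:
            collisions.append(f"{code}: {existing!r} vs {name!r}")
            continue
        entries[code] = name
    if collisions:
        raise DictionaryLoadError(
            "conflicting duplicate codes: " + "; ".join(collisions)
        )
    return VocabularyDictionary(vocabulary=vocab, entries=entries, code_pattern=code_pattern)


_CROSSMAP_HEADER = {"sourcevocab", "sourcevocabulary"}


def load_crossmap(source: str | TextIO) -> CrossMap:
    """Load a four-column crossmap (source vocab, source code, target vocab, target code).

    Link rows are stored with set semantics — duplicates collapse.  A row with
    a blank or unrecognized vocabulary token raises :class:`RowParseError`
    with its 0-based data-row index.
    """
    text = _read_text(source)
    delimiter = _delimiter_for(text)
    cm = CrossMap()
    index = 0
    for raw in csv.reader(io.StringIO(text), delimiter=delimiter):
        cells = [c.strip() for c in raw]
        if not any(cells):
            continue
        if _squash(cells[0]) in _CROSSMAP_HEADER:
            continue  # header row
        if len(cells) < 4:
            raise RowParseError(index, f"expected 4 columns, got {len(cells)}")
        sv, sc, tv, tc = cells[:4]
        for token in (sv, tv):
            if not token:
                raise RowParseError(index, "blank vocabulary token")
            if not VocabularyId.resolve(token).recognized:
                raise RowParseError(index, f"unknown vocabulary token {token!r}")
        try:
            cm.add(sv, sc, tv, tc)
        except MalformedCodeError as exc:
            raise RowParseError(index, str(exc)) from exc
        index += 1
    return cm


# ---------------------------------------------------------------------------
# Metric reports
# ---------------------------------------------------------------------------

class _AggregateModel(BaseModel):
    average: float
    min: float
    max: float


class _ReportRowModel(BaseModel):
    phenotype_name: str
    metrics: dict[str, float]
    diagnostics: list[str] = Field(default_factory=list)


class ReportModel(BaseModel):
    """Serialized form of a :class:`ReportDocument`; doubles as its JSON schema."""

    schema_version: int = 1
    rows: list[_ReportRowModel]
    aggregates: dict[str, _AggregateModel]


def report_json_schema() -> dict:
    """JSON Schema for the report document, derived from the pydantic model."""
    return ReportModel.model_json_schema()


def _round2(v: float) -> float:
    return round(v + 0.0, 2)


def _to_model(report: ReportDocument) -> ReportModel:
    rows = [
        _ReportRowModel(
            phenotype_name=r.phenotype_name,
            metrics={k: _round2(v) for k, v in r.present_metrics().items()},
            diagnostics=list(r.diagnostics),
        )
        for r in report.reports
    ]
    aggregates = {
        name: _AggregateModel(
            average=_round2(agg["average"]), min=_round2(agg["min"]), max=_round2(agg["max"])
        )
        for name, agg in report.aggregates.items()
    }
    return ReportModel(rows=rows, aggregates=aggregates)


def write_report(report: ReportDocument, format: str = "csv") -> str:
    """Serialize a report document; percentages rendered to two decimals.

    CSV layout: one row per phenotype with a column per metric, followed by
    ``average`` / ``minimum`` / ``maximum`` rows.  JSON output is validated
    against the shipped schema (via the pydantic model) before rendering.
    """
    model = _to_model(report)
    if format == "json":
        # validation round-trip: any schema violation raises here
        ReportModel.model_validate(model.model_dump())
        return model.model_dump_json(indent=2) + "\n"
    if format != "csv":
        raise ValueError(f"unsupported report format {format!r}")

    columns = ["phenotype"] + list(METRIC_FIELDS)
    records: list[dict[str, str]] = []
    for row in model.rows:
        rec = {"phenotype": row.phenotype_name}
        for m in METRIC_FIELDS:
            rec[m] = f"{row.metrics[m]:.2f}" if m in row.metrics else ""
        records.append(rec)
    for label, key in (("average", "average"), ("minimum", "min"), ("maximum", "max")):
        rec = {"phenotype": label}
        for m in METRIC_FIELDS:
            agg = model.aggregates.get(m)
            rec[m] = f"{getattr(agg, key):.2f}" if agg else ""
        records.append(rec)
    frame = pd.DataFrame.from_records(records, columns=columns)
    return frame.to_csv(index=False)


def read_report(text: str) -> ReportDocument:
    """Parse a JSON report written by :func:`write_report` back into a document."""
    model = ReportModel.model_validate(json.loads(text))
    reports = tuple(
        MetricReport(
            phenotype_name=row.phenotype_name,
            diagnostics=tuple(row.diagnostics),
            **{m: row.metrics.get(m) for m in METRIC_FIELDS},
        )
        for row in model.rows
    )
    aggregates = {
        name: {"average": agg.average, "min": agg.min, "max": agg.max}
        for name, agg in model.aggregates.items()
    }
    return ReportDocument(reports=reports, aggregates=aggregates)
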