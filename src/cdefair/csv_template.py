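"""The per-model CSV "lingua franca" contract and its validator.

Registries export one CSV file per CDE model.  The files follow the most
common dialect (comma separated, double-quote escaped, UTF-8, single header
row).  This module parses such exports, validates them against the model
template (strict ISO 8601 dates, full ontology IRIs, controlled value sets,
offline descendant-of checks against bundled term closures, unique row ids)
and mints timestamp-based row identifiers.  Validation reports issues as
data, never as exceptions, so a complete issue list is always produced.
"""

from __future__ import annotations

import csv
import datetime as _dt
import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Union

import yaml

from .catalog import (
    CatalogConfigError,
    ColumnSpec,
    DescendantOf,
    ModelTemplate,
    Regex,
    ValueSet,
)

__all__ = [
    "CsvParseError",
    "CsvTable",
    "RowRecord",
    "TermClosure",
    "ValidationIssue",
    "degrade_birth_dates",
    "issues_to_json",
    "issues_to_text",
    "load_term_closures",
    "mint_row_id",
    "parse_csv",
    "translate_labels",
    "validate_date",
    "validate_table",
    "validate_term",
    "write_csv",
]

_ISO_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")
_ABSOLUTE_IRI_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.-]*://\S+$|^urn:\S+$")

ISSUE_CODES = (
    "missing_required",
    "bad_date",
    "bad_iri",
    "not_in_value_set",
    "not_descendant",
    "duplicate_row_id",
    "bad_number",
)

_MESSAGE_TEMPLATES = {
    "missing_required": "required column {column!r} is empty",
    "bad_date": "value {value!r} in column {column!r} is not a strict "
    "ISO 8601 calendar date (YYYY-MM-DD)",
    "bad_iri": "value {value!r} in column {column!r} is not an absolute IRI",
    "not_in_value_set": "value {value!r} in column {column!r} is not in the "
    "allowed value set",
    "not_descendant": "value {value!r} in column {column!r} is not a "
    "descendant of {parent}",
    "duplicate_row_id": "row id {value!r} occurs more than once",
    "bad_number": "value {value!r} in column {column!r} is not a valid "
    "{kind} number",
}


class CsvParseError(ValueError):
    """Raised on structurally broken CSV input (with a line number)."""


@dataclass(frozen=True)
class ValidationIssue:
    row_id: str
    column: str
    code: str
    message: str

    @classmethod
    def make(cls, row_id: str, column: str, code: str, **ctx) -> "ValidationIssue":
        message = _MESSAGE_TEMPLATES[code].format(column=column, **ctx)
        return cls(row_id=row_id, column=column, code=code, message=message)


@dataclass(frozen=True)
class RowRecord:
    row_id: str
    pseudonym: str
    cells: Mapping[str, str]

    def get(self, column: str) -> str:
        return self.cells.get(column, "")


@dataclass(frozen=True)
class CsvTable:
    model_name: str
    header: tuple[str, ...]
    rows: tuple[RowRecord, ...]
    source_path: Optional[Path] = None
    parse_notes: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class TermClosure:
    """Descendant-or-self closures, parent IRI -> set of member IRIs."""

    closures: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for parent, members in self.closures.items():
            if parent not in members:
                raise CatalogConfigError(
                    f"closure for {parent} does not contain the parent itself"
                )

    def members(self, parent_iri: str) -> frozenset[str]:
        try:
            return self.closures[parent_iri]
        except KeyError:
            raise CatalogConfigError(
                f"no term closure configured for parent {parent_iri}"
            ) from None


def load_term_closures(extra_path: Optional[Union[str, Path]] = None) -> TermClosure:
    """Load the bundled sample closures, optionally merged with a user file."""
    text = (
        resources.files("cdefair") / "data" / "closures" / "term_closures.yaml"
    ).read_text("utf-8")
    raw = yaml.safe_load(text)
    closures = {
        str(parent): frozenset(str(m) for m in members)
        for parent, members in raw.items()
    }
    if extra_path is not None:
        extra = yaml.safe_load(Path(extra_path).read_text("utf-8")) or {}
        for parent, members in extra.items():
            merged = closures.get(str(parent), frozenset()) | {
                str(m) for m in members
            }
            closures[str(parent)] = merged | {str(parent)}
    return TermClosure(closures)


# ---------------------------------------------------------------------------
# Parsing


def parse_csv(path: Union[str, Path], template: ModelTemplate) -> CsvTable:
    """Parse a registry export for ``template``, preserving row order.

    Unknown extra columns are retained in the row cells and flagged in a
    parse note.  Cells are stripped of surrounding whitespace only.
    Structural problems (missing header, missing required columns, ragged
    rows, undecodable bytes) raise :class:`CsvParseError` with a line number.
    """
    path = Path(path)
    try:
        text = path.read_text("utf-8")
    except UnicodeDecodeError as exc:
        raise CsvParseError(f"{path}: not valid UTF-8 ({exc})") from exc
    reader = csv.reader(text.splitlines())
    try:
        header = next(reader)
    except StopIteration:
        raise CsvParseError(f"{path}: line 1: missing header row") from None
    header = tuple(h.strip() for h in header)
    if len(set(header)) != len(header):
        raise CsvParseError(f"{path}: line 1: duplicate column names in header")
    missing = [c for c in template.required_columns if c not in header]
    if missing:
        raise CsvParseError(
            f"{path}: line 1: header is missing required column(s) "
            f"{', '.join(missing)} for model {template.model_name}"
        )
    known = {c.name for c in template.column_specs}
    extra = [c for c in header if c not in known]
    notes = (f"extra columns retained: {extra}",) if extra else ()

    rows = []
    for lineno, record in enumerate(reader, start=2):
        if not record:
            continue  # blank line
        if len(record) != len(header):
            raise CsvParseError(
                f"{path}: line {lineno}: expected {len(header)} fields, "
                f"found {len(record)}"
            )
        cells = {name: value.strip() for name, value in zip(header, record)}
        rows.append(
            RowRecord(
                row_id=cells.get("row_id", ""),
                pseudonym=cells.get("pid", ""),
                cells=cells,
            )
        )
    return CsvTable(
        model_name=template.model_name,
        header=header,
        rows=tuple(rows),
        source_path=path,
        parse_notes=notes,
    )


def write_csv(table: CsvTable, path: Union[str, Path]) -> Path:
    """Write a table back out in the canonical dialect (deterministic)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as handle:
        writer = csv.writer(handle, lineterminator="\n")
        writer.writerow(table.header)
        for row in table.rows:
            writer.writerow([row.cells.get(col, "") for col in table.header])
    return path


# ---------------------------------------------------------------------------
# Cell validators


def validate_date(value: str) -> bool:
    """True iff ``value`` is a calendar-valid strict ISO 8601 date.

    Only the extended YYYY-MM-DD form is accepted: no time component, no
    compact (YYYYMMDD) or week-date dialects, no slash dialects.  Total
    function; never raises.
    """
    if not isinstance(value, str) or not _ISO_DATE_RE.match(value):
        return False
    year, month, day = (int(part) for part in value.split("-"))
    try:
        _dt.date(year, month, day)
    except ValueError:
        return False
    return True


def validate_term(value: str, constraint: DescendantOf, closure: TermClosure) -> bool:
    """True iff ``value`` is an absolute IRI inside the parent's closure.

    The parent itself counts (descendant-or-self).  A missing closure for
    the constraint's parent is a configuration error, not a data issue.
    """
    members = closure.members(constraint.parent_iri)
    if not _ABSOLUTE_IRI_RE.match(value or ""):
        return False
    return value in members


def _check_cell(
    spec: ColumnSpec, value: str, row_id: str, closures: TermClosure
) -> list[ValidationIssue]:
    issues: list[ValidationIssue] = []
    if spec.datatype == "iso_date":
        if not validate_date(value):
            issues.append(
                ValidationIssue.make(row_id, spec.name, "bad_date", value=value)
            )
        return issues
    if spec.datatype == "iri" and not _ABSOLUTE_IRI_RE.match(value):
        issues.append(
            ValidationIssue.make(row_id, spec.name, "bad_iri", value=value)
        )
        return issues
    if spec.datatype in ("decimal", "integer"):
        pattern = r"[+-]?\d+" if spec.datatype == "integer" else r"[+-]?(\d+(\.\d*)?|\.\d+)"
        if not re.fullmatch(pattern, value):
            issues.append(
                ValidationIssue.make(
                    row_id, spec.name, "bad_number", value=value, kind=spec.datatype
                )
            )
            return issues
    constraint = spec.constraint
    if isinstance(constraint, ValueSet) and value not in constraint.values:
        issues.append(
            ValidationIssue.make(row_id, spec.name, "not_in_value_set", value=value)
        )
    elif isinstance(constraint, DescendantOf):
        if not validate_term(value, constraint, closures):
            issues.append(
                ValidationIssue.make(
                    row_id,
                    spec.name,
                    "not_descendant",
                    value=value,
                    parent=constraint.parent_iri,
                )
            )
    elif isinstance(constraint, Regex) and not constraint.matches(value):
        # No dedicated code for pattern violations; they are value-set misses.
        issues.append(
            ValidationIssue.make(row_id, spec.name, "not_in_value_set", value=value)
        )
    return issues


def validate_table(
    table: CsvTable,
    template: ModelTemplate,
    closures: Optional[TermClosure] = None,
) -> list[ValidationIssue]:
    """Validate every cell of ``table`` against the model contract.

    Returns ALL issues (not first failure); an empty list means the table
    fully conforms.  Duplicate row ids are reported once per participating
    row.  Non-required empty cells are simply absent values and produce no
    issues.
    """
    if closures is None:
        closures = load_term_closures()
    issues: list[ValidationIssue] = []

    seen: dict[str, int] = {}
    for row in table.rows:
        seen[row.row_id] = seen.get(row.row_id, 0) + 1
    for row in table.rows:
        if row.row_id and seen[row.row_id] > 1:
            issues.append(
                ValidationIssue.make(
                    row.row_id, "row_id", "duplicate_row_id", value=row.row_id
                )
            )

    for row in table.rows:
        for spec in template.column_specs:
            value = row.get(spec.name)
            if value == "":
                if spec.required:
                    issues.append(
                        ValidationIssue.make(
                            row.row_id, spec.name, "missing_required"
                        )
                    )
                continue
            issues.extend(_check_cell(spec, value, row.row_id, closures))
        for group in template.at_least_one_of:
            if all(row.get(col) == "" for col in group):
                issues.append(
                    ValidationIssue.make(row.row_id, group[0], "missing_required")
                )
    return issues


# ---------------------------------------------------------------------------
# Identifier minting


def mint_row_id(clock: _dt.datetime, sequence: int) -> str:
    """Deterministic, filesystem- and IRI-safe row identifier.

    Mirrors a timestamp-based GUID service: the identifier is an opaque
    function of (clock, sequence); distinct inputs give distinct outputs.
    """
    if sequence < 0:
        raise ValueError("sequence must be non-negative")
    stamp = clock.strftime("%Y%m%dT%H%M%S") + f"{clock.microsecond:06d}"
    return f"R{stamp}-{sequence:06d}"


# ---------------------------------------------------------------------------
# Optional pre-processing helpers (off by default in the pipeline)


def translate_labels(table: CsvTable, template: ModelTemplate, catalog) -> CsvTable:
    """Replace controlled labels by their bound IRIs in value-set columns.

    Custodian rules require IRIs in the export; this helper repairs exports
    that still carry bare labels (e.g. "Male").  It only touches cells whose
    text is a known label for the column's source element.
    """
    label_maps: dict[str, Mapping[str, str]] = {}
    for spec in template.column_specs:
        if isinstance(spec.constraint, ValueSet) and spec.constraint.element_id:
            label_maps[spec.name] = catalog.bindings[spec.constraint.element_id]
    if not label_maps:
        return table
    new_rows = []
    for row in table.rows:
        cells = dict(row.cells)
        for column, mapping in label_maps.items():
            if cells.get(column) in mapping:
                cells[column] = mapping[cells[column]]
        new_rows.append(replace(row, cells=cells))
    return replace(table, rows=tuple(new_rows))


def degrade_birth_dates(table: CsvTable, column: str = "birth_date") -> CsvTable:
    """Privacy degradation: reduce a date column to its year (YYYY).

    Offered for the personal-information model where emitting the full
    birth date may be too identifying; selected via the run configuration
    (default is the date as given).
    """
    new_rows = []
    for row in table.rows:
        cells = dict(row.cells)
        value = cells.get(column, "")
        if validate_date(value):
            cells[column] = value[:4]
        new_rows.append(replace(row, cells=cells))
    return replace(table, rows=tuple(new_rows))


# ---------------------------------------------------------------------------
# Issue report serialization


def issues_to_json(issues: Iterable[ValidationIssue]) -> str:
    return json.dumps(
        [
            {
                "row_id": i.row_id,
                "column": i.column,
                "code": i.code,
                "message": i.message,
            }
            for i in issues
        ],
        indent=2,
    )


def issues_to_text(issues: Iterable[ValidationIssue]) -> str:
    lines = [f"[{i.code}] row {i.row_id} / {i.column}: {i.message}" for i in issues]
    return "\n".join(lines) if lines else "no issues"
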