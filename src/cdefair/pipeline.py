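"""Service-free orchestration: discover CSVs, transform, validate, replace-load.

A run scans a folder of registry CSV exports, matches each file to a CDE
model by filename prefix, validates it against the model contract,
transforms it to RDF (direct builder by default, mapping-executor mode
selectable), ShEx-validates the result, and then atomically replaces the
output store — a folder of sorted N-Triples files standing in for a triple
store repository.  All previous store content is deleted before the
refreshed data lands, so the store is always a pure function of the final
input folder.  In strict mode any validation issue aborts the run before
the store is touched.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
import shutil
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Union

import yaml

from .catalog import Catalog, load_catalog
from .csv_template import (
    CsvParseError,
    CsvTable,
    TermClosure,
    ValidationIssue,
    degrade_birth_dates,
    load_term_closures,
    parse_csv,
    validate_table,
)
from .mapping import execute_mapping, generate_mapping
from .shex import generate_shape, validate_graph
from .sio_graph import (
    DEFAULT_BASE_IRI,
    TripleSet,
    load_vocabulary,
    serialize,
    transform_table,
)

__all__ = [
    "DiscoveryReport",
    "PipelineConfigError",
    "RunConfig",
    "RunReport",
    "ValidationAbort",
    "discover",
    "run",
]

logger = logging.getLogger("cdefair.pipeline")

_XSD = "http://www.w3.org/2001/XMLSchema#"


class PipelineConfigError(ValueError):
    """Configuration or IO failure (CLI exit code 2)."""


class ValidationAbort(RuntimeError):
    """Strict-mode abort; carries the report of what was found."""

    def __init__(self, report: "RunReport"):
        super().__init__("validation issues found in strict mode; store untouched")
        self.report = report


@dataclass(frozen=True)
class DiscoveryReport:
    matches: Mapping[Path, str]  # file -> model_name
    unmatched: tuple[Path, ...]


def discover(folder: Union[str, Path], catalog: Catalog) -> DiscoveryReport:
    """Match each CSV in ``folder`` to a model by filename prefix.

    A file matches model *m* iff its basename, lowercased and with
    separators normalized to underscores, starts with *m*'s name.  Longer
    model names win (so ``genetic_diagnosis_2021.csv`` is not claimed by
    ``diagnosis``).  Unmatched CSVs are reported, never silently skipped.
    """
    folder = Path(folder)
    if not folder.is_dir():
        raise PipelineConfigError(f"not a readable folder: {folder}")
    names = sorted(catalog.models, key=len, reverse=True)
    matches: dict[Path, str] = {}
    unmatched: list[Path] = []
    for path in sorted(folder.glob("*.csv")):
        stem = re.sub(r"[\s\-]+", "_", path.name.lower())
        model = next((n for n in names if stem.startswith(n)), None)
        if model is None:
            unmatched.append(path)
        else:
            matches[path] = model
    return DiscoveryReport(matches=matches, unmatched=tuple(unmatched))


@dataclass(frozen=True)
class RunConfig:
    strict: bool = True
    mode: str = "builder"  # builder | mapping
    deterministic: bool = True
    base_iri: str = DEFAULT_BASE_IRI
    birth_date_as_year: bool = False
    bindings_overrides: Optional[dict] = None
    vocabulary_overrides: Optional[dict] = None

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **kwargs) -> "RunConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text("utf-8")) or {}
        except (OSError, yaml.YAMLError) as exc:
            raise PipelineConfigError(f"cannot read config {path}: {exc}") from exc
        privacy = raw.get("privacy") or {}
        return cls(
            base_iri=raw.get("base_iri", DEFAULT_BASE_IRI),
            birth_date_as_year=bool(privacy.get("birth_date_as_year", False)),
            bindings_overrides=raw.get("bindings"),
            vocabulary_overrides=raw.get("vocabulary"),
            **kwargs,
        )


@dataclass
class FileReport:
    file: str
    model: str
    rows: int = 0
    issues: int = 0
    skipped_rows: int = 0
    triples: int = 0
    focus_nodes: int = 0
    nonconforming: int = 0
    issue_details: list = field(default_factory=list)


@dataclass
class RunReport:
    mode: str
    strict: bool
    store: str
    files: list[FileReport] = field(default_factory=list)
    unmatched: list[str] = field(default_factory=list)
    aborted: bool = False

    @property
    def total_issues(self) -> int:
        return sum(f.issues for f in self.files)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _privacy_template(template):
    """Swap the birth-date literal to xsd:gYear for year-only emission."""
    outputs = tuple(
        replace(
            out,
            literals=tuple(
                replace(lit, datatype="xsd:gYear")
                if lit.column == "birth_date"
                else lit
                for lit in out.literals
            ),
        )
        for out in template.outputs
    )
    return replace(template, outputs=outputs)


def run(
    folder: Union[str, Path],
    out_store: Union[str, Path],
    config: Optional[RunConfig] = None,
    *,
    catalog: Optional[Catalog] = None,
    closures: Optional[TermClosure] = None,
) -> RunReport:
    """Execute the full transformation over a folder of CSV exports.

    Raises :class:`ValidationAbort` (store untouched) when strict mode
    finds issues, :class:`PipelineConfigError` for configuration/IO
    problems.  The store directory is replaced atomically via a temporary
    sibling directory and rename, so a crash never leaves a partial store.
    """
    config = config or RunConfig()
    if config.mode not in ("builder", "mapping"):
        raise PipelineConfigError(f"unknown mode {config.mode!r}")
    if catalog is None:
        catalog = load_catalog(
            config={"bindings": config.bindings_overrides}
            if config.bindings_overrides
            else None
        )
    closures = closures or load_term_closures()
    vocab = load_vocabulary(config.vocabulary_overrides)
    out_store = Path(out_store)

    discovery = discover(folder, catalog)
    if not discovery.matches:
        raise PipelineConfigError(f"no CSV files matched any model in {folder}")
    report = RunReport(
        mode=config.mode,
        strict=config.strict,
        store=str(out_store),
        unmatched=[str(p) for p in discovery.unmatched],
    )

    # Phase 1: parse + validate everything before any store mutation.
    staged: list[tuple[str, CsvTable]] = []
    for path, model in discovery.matches.items():
        template = catalog.get_model(model)
        try:
            table = parse_csv(path, template)
        except CsvParseError as exc:
            raise PipelineConfigError(str(exc)) from exc
        issues = validate_table(table, template, closures)
        if issues and not config.strict:
            # Lenient mode: transform the clean rows, report the rest.
            flagged = {i.row_id for i in issues}
            kept = tuple(r for r in table.rows if r.row_id not in flagged)
            skipped = len(table.rows) - len(kept)
            table = replace(table, rows=kept)
        else:
            skipped = 0
        file_report = FileReport(
            file=str(path),
            model=model,
            rows=len(table),
            issues=len(issues),
            skipped_rows=skipped,
            issue_details=[
                {"row_id": i.row_id, "column": i.column, "code": i.code}
                for i in issues[:100]
            ],
        )
        report.files.append(file_report)
        staged.append((model, table))
    if config.strict and report.total_issues:
        report.aborted = True
        logger.error(
            "strict mode: %d validation issue(s); aborting before store mutation",
            report.total_issues,
        )
        raise ValidationAbort(report)

    # Phase 2: transform and ShEx-validate per file, accumulating per model.
    graphs: dict[str, TripleSet] = {}
    for file_report, (model, table) in zip(report.files, staged):
        template = catalog.get_model(model)
        if config.birth_date_as_year and model == "personal_information":
            template = _privacy_template(template)
            table = degrade_birth_dates(table)
        if config.mode == "builder":
            ts = transform_table(
                template, table, base_iri=config.base_iri, vocab=vocab
            )
        else:
            doc = generate_mapping(template, base_iri=config.base_iri)
            ts = execute_mapping(doc, table)
        schema = generate_shape(template, base_iri=config.base_iri)
        conformance = validate_graph(schema, ts)
        file_report.triples = len(ts)
        file_report.focus_nodes = conformance.summary["focus_nodes"]
        file_report.nonconforming = conformance.summary["nonconforming"]
        graphs[model] = graphs.get(model, TripleSet(frozenset())) | ts
        logger.info(
            "%s: %d rows -> %d triples, %d/%d focus nodes conform",
            file_report.file,
            file_report.rows,
            file_report.triples,
            conformance.summary["conforming"],
            conformance.summary["focus_nodes"],
        )

    # Phase 3: replace-load. Build aside, then swap.
    temp = out_store.with_name(out_store.name + ".staging")
    if temp.exists():
        shutil.rmtree(temp)
    temp.mkdir(parents=True)
    for model, ts in sorted(graphs.items()):
        text = serialize(ts, "ntriples", deterministic=config.deterministic)
        (temp / f"{model}.nt").write_text(text, encoding="utf-8")
    if out_store.exists():
        shutil.rmtree(out_store)
    temp.rename(out_store)
    return report
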