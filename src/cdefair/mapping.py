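"""Declarative CSV-to-RDF mappings: generation, YARRRML (de)serialization
and execution of the RML subset the CDE patterns need.

A mapping document holds one logical source (the model's CSV file, iterated
per row) and one triple map per pattern node.  Subject, predicate and object
positions are strings that may contain ``$(column)`` variables; during
execution every variable is replaced by the value of that column within a
single row, then the source is iterated over all rows.  Pairs that
reference an empty cell are suppressed; values substituted into IRI
templates are percent-encoded, while an object that is exactly one variable
is taken verbatim as an IRI reference.

Only the subset needed here is executed: row iteration, template
substitution, datatyped literals, and cross-map references (resolved as the
referenced map's subject template over the same row, which subsumes the
join-on-shared-column semantics for these per-row tree patterns).  No
functions or conditions.  Executing the generated document reproduces the
direct builder's output graph exactly; that equivalence is the module's
central property and is asserted in the test suite.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union
from urllib.parse import quote

import yaml

from .catalog import ModelTemplate
from .csv_template import CsvTable
from .sio_graph import (
    DEFAULT_BASE_IRI,
    GraphPattern,
    Literal,
    RDF_TYPE,
    TripleSet,
    build_core_pattern,
    specialize,
)

__all__ = [
    "ColumnLiteral",
    "IriTemplate",
    "MapRef",
    "MappingDoc",
    "MappingError",
    "TripleMap",
    "execute_mapping",
    "generate_mapping",
    "parse_yarrrml",
    "serialize_yarrrml",
]

_XSD_PREFIX = "http://www.w3.org/2001/XMLSchema#"
_VAR_RE = re.compile(r"\$\(([^)]+)\)")


class MappingError(ValueError):
    """Raised on generation, parsing or execution failures."""


@dataclass(frozen=True)
class IriTemplate:
    """An object (or subject) IRI template with ``$(column)`` variables."""

    template: str


@dataclass(frozen=True)
class ColumnLiteral:
    column: str
    datatype: str  # full datatype IRI


@dataclass(frozen=True)
class MapRef:
    name: str


ObjectSpec = Union[IriTemplate, ColumnLiteral, MapRef]


@dataclass(frozen=True)
class TripleMap:
    name: str
    subject_template: str
    type_assertions: tuple[str, ...] = ()
    predicate_object_pairs: tuple[tuple[str, ObjectSpec], ...] = ()


@dataclass(frozen=True)
class MappingDoc:
    model_name: str
    source: str  # logical source file reference, row iterator implied
    triple_maps: tuple[TripleMap, ...]
    prefixes: Mapping[str, str] = field(default_factory=dict)

    def map(self, name: str) -> TripleMap:
        for tm in self.triple_maps:
            if tm.name == name:
                return tm
        raise KeyError(name)


# ---------------------------------------------------------------------------
# Generation from a model template


def _to_var_template(iri_rule: str, model: str, base_iri: str) -> str:
    if iri_rule.startswith("@col:"):
        return f"$({iri_rule[5:]})"
    out = iri_rule.replace("{base}", base_iri).replace("{model}", model)
    out = re.sub(r"\{col:([^}]+)\}", r"$(\1)", out)
    out = out.replace("{pid}", "$(pid)").replace("{row_id}", "$(row_id)")
    unresolved = re.findall(r"\{([^}]+)\}", out)
    if unresolved:
        raise MappingError(f"unbound pattern slots {unresolved} in {iri_rule!r}")
    return out


def _map_name(node_id: str) -> str:
    return node_id.replace(":", "_")


def generate_mapping(
    template: ModelTemplate,
    *,
    base_iri: str = DEFAULT_BASE_IRI,
    pattern: Optional[GraphPattern] = None,
) -> MappingDoc:
    """Generate the declarative mapping document for one model.

    Executing the result over a table reproduces the direct builder's
    ``transform_table`` semantics for that model.  Generation is
    deterministic: regenerating yields an identical document.
    """
    if pattern is None:
        pattern = specialize(build_core_pattern(), template, base_iri=base_iri)
    maps = []
    for node in pattern.nodes:
        name = _map_name(node.node_id)
        subject = _to_var_template(node.iri_rule, pattern.model_name, base_iri)
        types = [node.base_type_iri]
        if node.specific_type:
            types.append(node.specific_type)
        pairs: list[tuple[str, ObjectSpec]] = []
        if node.type_column:
            pairs.append((RDF_TYPE, IriTemplate(f"$({node.type_column})")))
        for edge in pattern.edges:
            if edge.subject == node.node_id:
                pairs.append((edge.predicate, MapRef(_map_name(edge.object))))
        for slot in pattern.literal_slots:
            if slot.node == node.node_id:
                pairs.append((slot.property, ColumnLiteral(slot.column, slot.datatype)))
        maps.append(
            TripleMap(
                name=name,
                subject_template=subject,
                type_assertions=tuple(types),
                predicate_object_pairs=tuple(pairs),
            )
        )
    return MappingDoc(
        model_name=pattern.model_name,
        source=f"{pattern.model_name}.csv",
        triple_maps=tuple(maps),
        prefixes=dict(pattern.namespaces),
    )


# ---------------------------------------------------------------------------
# YARRRML serialization


def _dt_curie(datatype_iri: str) -> str:
    if datatype_iri.startswith(_XSD_PREFIX):
        return "xsd:" + datatype_iri[len(_XSD_PREFIX):]
    return datatype_iri


def _dt_iri(curie_or_iri: str) -> str:
    if curie_or_iri.startswith("xsd:"):
        return _XSD_PREFIX + curie_or_iri[4:]
    return curie_or_iri


def serialize_yarrrml(doc: MappingDoc) -> str:
    """Render the document in the YARRRML YAML dialect (mappings/sources/s/po)."""
    mappings: dict = {}
    for tm in doc.triple_maps:
        po: list = [["a", f"{t}~iri"] for t in tm.type_assertions]
        for predicate, obj in tm.predicate_object_pairs:
            pred_key = "a" if predicate == RDF_TYPE else predicate
            if isinstance(obj, IriTemplate):
                po.append([pred_key, f"{obj.template}~iri"])
            elif isinstance(obj, MapRef):
                po.append([pred_key, {"mapping": obj.name}])
            else:
                po.append(
                    [
                        pred_key,
                        {"value": f"$({obj.column})", "datatype": _dt_curie(obj.datatype)},
                    ]
                )
        mappings[tm.name] = {
            "sources": [[f"{doc.source}~csv"]],
            "s": tm.subject_template,
            "po": po,
        }
    data = {
        "prefixes": dict(doc.prefixes),
        "mappings": mappings,
    }
    return yaml.safe_dump(data, sort_keys=False, default_flow_style=None, width=4096)


_KNOWN_DOC_KEYS = {"prefixes", "mappings"}
_KNOWN_MAP_KEYS = {"sources", "s", "po"}


def parse_yarrrml(text: str) -> MappingDoc:
    """Parse a YARRRML document of the dialect emitted by serialize_yarrrml.

    Unknown keys are rejected loudly rather than ignored.
    """
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise MappingError("YARRRML document must be a YAML mapping")
    unknown = set(data) - _KNOWN_DOC_KEYS
    if unknown:
        raise MappingError(f"unknown YARRRML keys: {sorted(unknown)}")
    prefixes = dict(data.get("prefixes") or {})
    sources = set()
    maps = []
    for name, raw in (data.get("mappings") or {}).items():
        unknown = set(raw) - _KNOWN_MAP_KEYS
        if unknown:
            raise MappingError(f"mapping {name!r}: unknown keys {sorted(unknown)}")
        for src in raw.get("sources", ()):
            ref = src[0] if isinstance(src, list) else src
            if not str(ref).endswith("~csv"):
                raise MappingError(f"mapping {name!r}: unsupported source {ref!r}")
            sources.add(str(ref)[: -len("~csv")])
        types = []
        pairs: list[tuple[str, ObjectSpec]] = []
        for entry in raw.get("po", ()):
            if not (isinstance(entry, list) and len(entry) == 2):
                raise MappingError(f"mapping {name!r}: bad po entry {entry!r}")
            pred, obj = entry
            predicate = RDF_TYPE if pred == "a" else str(pred)
            if isinstance(obj, str) and obj.endswith("~iri"):
                value = obj[: -len("~iri")]
                if predicate == RDF_TYPE and "$(" not in value:
                    types.append(value)
                else:
                    pairs.append((predicate, IriTemplate(value)))
            elif isinstance(obj, dict) and "mapping" in obj:
                pairs.append((predicate, MapRef(str(obj["mapping"]))))
            elif isinstance(obj, dict) and "value" in obj:
                match = _VAR_RE.fullmatch(str(obj["value"]))
                if not match:
                    raise MappingError(
                        f"mapping {name!r}: literal value must be one variable"
                    )
                pairs.append(
                    (predicate, ColumnLiteral(match.group(1), _dt_iri(obj["datatype"])))
                )
            else:
                raise MappingError(f"mapping {name!r}: bad object spec {obj!r}")
        maps.append(
            TripleMap(
                name=str(name),
                subject_template=str(raw["s"]),
                type_assertions=tuple(types),
                predicate_object_pairs=tuple(pairs),
            )
        )
    if len(sources) != 1:
        raise MappingError(f"expected one logical source, found {sorted(sources)}")
    source = sources.pop()
    model_name = source[: -len(".csv")] if source.endswith(".csv") else source
    return MappingDoc(
        model_name=model_name,
        source=source,
        triple_maps=tuple(maps),
        prefixes=prefixes,
    )


# ---------------------------------------------------------------------------
# Execution


def _resolve_template(template: str, cells: Mapping[str, str], row_id: str) -> Optional[str]:
    """Substitute variables; None if any referenced cell is empty."""
    single = _VAR_RE.fullmatch(template)
    if single:
        column = single.group(1)
        if column not in cells:
            raise MappingError(f"row {row_id!r}: unresolvable column {column!r}")
        return cells[column] or None  # verbatim IRI reference

    absent = False

    def substitute(match: re.Match) -> str:
        nonlocal absent
        column = match.group(1)
        if column not in cells:
            raise MappingError(f"row {row_id!r}: unresolvable column {column!r}")
        value = cells[column]
        if not value:
            absent = True
            return ""
        return quote(value, safe="")

    resolved = _VAR_RE.sub(substitute, template)
    return None if absent else resolved


def execute_mapping(doc: MappingDoc, table: CsvTable) -> TripleSet:
    """Run the document over a table: per-row substitution, union over rows."""
    by_name = {tm.name: tm for tm in doc.triple_maps}
    triples = set()
    for row in table.rows:
        subjects = {
            name: _resolve_template(tm.subject_template, row.cells, row.row_id)
            for name, tm in by_name.items()
        }
        for tm in doc.triple_maps:
            subject = subjects[tm.name]
            if subject is None:
                continue
            for type_iri in tm.type_assertions:
                triples.add((subject, RDF_TYPE, type_iri))
            for predicate, obj in tm.predicate_object_pairs:
                if isinstance(obj, IriTemplate):
                    value = _resolve_template(obj.template, row.cells, row.row_id)
                    if value is not None:
                        triples.add((subject, predicate, value))
                elif isinstance(obj, MapRef):
                    if obj.name not in subjects:
                        raise MappingError(
                            f"row {row.row_id!r}: reference to unknown map "
                            f"{obj.name!r}"
                        )
                    target = subjects[obj.name]
                    if target is not None:
                        triples.add((subject, predicate, target))
                else:
                    if obj.column not in row.cells:
                        raise MappingError(
                            f"row {row.row_id!r}: unresolvable column "
                            f"{obj.column!r}"
                        )
                    value = row.cells[obj.column]
                    if value:
                        triples.add((subject, predicate, Literal(value, obj.datatype)))
    return TripleSet(frozenset(triples), dict(doc.prefixes))
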