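"""The five-element SIO core pattern and its per-model RDF instantiation.

The core pattern connects five primary element categories — identifiers,
entities (a person and the information-content outputs of a process), roles,
processes, and attributes — with the minimal relation set:

* the person connects to the clinical process only indirectly, through the
  role they play in it;
* the pseudonym identifier attaches to that role, never to the person
  directly (one individual may hold many roles, each with its own id);
* the process has one or more information-content outputs;
* each output refers to an attribute of the person (the attribute and its
  measurement are distinct things).

Every node carries a base ontological type; model templates specialize the
pattern with more specific types, literal slots bound to CSV columns, and —
for diagnosis-linked models — an edge into the per-(patient, episode)
disease-progression container node.  Node IRIs are deterministic functions
of (base IRI, model, pseudonym or row id, slot), so re-running a
transformation reproduces identical graphs; blank nodes are never used.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Iterable, Mapping, Optional, Union
from urllib.parse import quote

import yaml
from rdflib import Graph, Literal as RLiteral, Namespace, URIRef
from rdflib.namespace import RDF, XSD

from .catalog import ModelTemplate
from .csv_template import CsvTable, RowRecord

__all__ = [
    "DEFAULT_BASE_IRI",
    "Edge",
    "GraphPattern",
    "InstantiationError",
    "Literal",
    "LiteralSlotPattern",
    "NodePattern",
    "PatternError",
    "Triple",
    "TripleSet",
    "build_core_pattern",
    "extend_body_measurement",
    "extend_lab_measurement",
    "extend_prom",
    "from_rdflib",
    "instantiate",
    "load_vocabulary",
    "serialize",
    "specialize",
    "to_rdflib",
    "transform_table",
]

RDF_TYPE = str(RDF.type)
DEFAULT_BASE_IRI = "https://example.org/registry/"

PRIMARY_ELEMENT_CATEGORIES = {
    "person_entity": "entity",
    "output_entity": "entity",
    "role": "role",
    "process": "process",
    "attribute": "attribute",
    "identifier": "identifier",
}

_XSD_PREFIX = "http://www.w3.org/2001/XMLSchema#"


class PatternError(ValueError):
    """Raised when a pattern cannot be constructed for a template."""


class InstantiationError(ValueError):
    """Raised when a row cannot fill a pattern (names the failing slot)."""


def _xsd_iri(curie_or_iri: str) -> str:
    if curie_or_iri.startswith("xsd:"):
        return _XSD_PREFIX + curie_or_iri[4:]
    return curie_or_iri


def load_vocabulary(overrides: Optional[Mapping] = None) -> dict:
    """Load the bundled relation/base-type vocabulary (slot name -> IRI)."""
    text = (resources.files("cdefair") / "data" / "vocabulary.yaml").read_text(
        "utf-8"
    )
    vocab = yaml.safe_load(text)
    if overrides:
        for section in ("relations", "base_types", "prefixes"):
            for key, value in (overrides.get(section) or {}).items():
                if key not in vocab[section]:
                    raise PatternError(
                        f"vocabulary override: unknown {section} slot {key!r}"
                    )
                vocab[section][key] = str(value)
    return vocab


# ---------------------------------------------------------------------------
# Pattern model


@dataclass(frozen=True)
class NodePattern:
    """One node of a graph pattern.

    ``iri_rule`` is a template over ``{base}``, ``{model}``, ``{pid}``,
    ``{row_id}`` and ``{col:<column>}`` placeholders; column and identifier
    substitutions are percent-encoded.  The special form ``@col:<column>``
    takes the (already-IRI) cell value verbatim as the node IRI.  A node
    whose rule references an empty cell is simply absent for that row,
    together with its edges and literal slots.
    """

    node_id: str
    kind: str  # person_entity | output_entity | role | process | attribute | identifier
    base_type_iri: str
    iri_rule: str
    specific_type: Optional[str] = None  # fixed additional rdf:type
    type_column: Optional[str] = None  # per-row additional rdf:type
    value_parent: Optional[str] = None  # documented class constraint, if any

    def __post_init__(self) -> None:
        if self.kind not in PRIMARY_ELEMENT_CATEGORIES:
            raise PatternError(f"unknown node kind {self.kind!r}")
        if not self.base_type_iri:
            raise PatternError(f"node {self.node_id}: missing base type")

    @property
    def category(self) -> str:
        return PRIMARY_ELEMENT_CATEGORIES[self.kind]

    @property
    def referenced_columns(self) -> tuple[str, ...]:
        if self.iri_rule.startswith("@col:"):
            return (self.iri_rule[5:],)
        return tuple(re.findall(r"\{col:([^}]+)\}", self.iri_rule))


@dataclass(frozen=True)
class Edge:
    subject: str  # node_id
    predicate: str  # IRI
    object: str  # node_id


@dataclass(frozen=True)
class LiteralSlotPattern:
    node: str  # node_id
    property: str  # predicate IRI
    column: str
    datatype: str  # datatype IRI
    required: bool = False


@dataclass(frozen=True)
class GraphPattern:
    pattern_id: str
    model_name: str
    nodes: tuple[NodePattern, ...]
    edges: tuple[Edge, ...]
    literal_slots: tuple[LiteralSlotPattern, ...]
    namespaces: Mapping[str, str] = field(default_factory=dict)
    vocab: Mapping = field(default_factory=dict, compare=False)

    def node(self, node_id: str) -> NodePattern:
        for node in self.nodes:
            if node.node_id == node_id:
                return node
        raise KeyError(node_id)

    def node_ids(self) -> tuple[str, ...]:
        return tuple(n.node_id for n in self.nodes)


# ---------------------------------------------------------------------------
# Triples


@dataclass(frozen=True)
class Literal:
    lexical: str
    datatype: str  # datatype IRI


Triple = tuple  # (subject IRI, predicate IRI, object IRI-or-Literal)


@dataclass(frozen=True)
class TripleSet:
    triples: frozenset
    namespaces: Mapping[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.triples)

    def __or__(self, other: "TripleSet") -> "TripleSet":
        namespaces = {**self.namespaces, **other.namespaces}
        return TripleSet(self.triples | other.triples, namespaces)

    def subjects_with_type(self, type_iri: str) -> set[str]:
        return {s for s, p, o in self.triples if p == RDF_TYPE and o == type_iri}


def to_rdflib(ts: TripleSet) -> Graph:
    graph = Graph()
    for prefix, iri in ts.namespaces.items():
        graph.bind(prefix, Namespace(iri))
    for s, p, o in ts.triples:
        if isinstance(o, Literal):
            obj = RLiteral(o.lexical, datatype=URIRef(o.datatype))
        else:
            obj = URIRef(o)
        graph.add((URIRef(s), URIRef(p), obj))
    return graph


def from_rdflib(graph: Graph) -> TripleSet:
    triples = set()
    for s, p, o in graph:
        if isinstance(o, RLiteral):
            datatype = str(o.datatype) if o.datatype else _XSD_PREFIX + "string"
            obj: Union[str, Literal] = Literal(str(o), datatype)
        else:
            obj = str(o)
        triples.add((str(s), str(p), obj))
    namespaces = {prefix: str(iri) for prefix, iri in graph.namespaces()}
    return TripleSet(frozenset(triples), namespaces)


def serialize(ts: TripleSet, format: str = "turtle", deterministic: bool = False) -> str:
    """Serialize to Turtle or N-Triples; round-trip stable.

    With ``deterministic=True`` the N-Triples lines are sorted so repeated
    runs produce byte-identical output (the replace-load store relies on
    this).
    """
    if format not in ("turtle", "ntriples"):
        raise ValueError(f"unsupported format {format!r}")
    graph = to_rdflib(ts)
    if format == "turtle":
        return graph.serialize(format="turtle")
    text = graph.serialize(format="nt")
    if deterministic:
        lines = sorted(line for line in text.splitlines() if line.strip())
        return "\n".join(lines) + "\n"
    return text


# ---------------------------------------------------------------------------
# Core pattern


def build_core_pattern(vocab: Optional[Mapping] = None) -> GraphPattern:
    """The model-independent five-element core pattern.

    Six node kinds cover the five primary element categories (the entity
    category contributes both the person and the process output).  The
    process node is always typed with the generic process class; every other
    node likewise carries a base type so that all nodes stay ontologically
    typed even before specialization.
    """
    vocab = vocab or load_vocabulary()
    rel = vocab["relations"]
    base_t = vocab["base_types"]
    nodes = (
        NodePattern("person", "person_entity", base_t["person"], "{base}person/{pid}"),
        NodePattern("role", "role", base_t["role"], "{base}person/{pid}/role"),
        NodePattern(
            "identifier", "identifier", base_t["identifier"], "{base}person/{pid}/id"
        ),
        NodePattern("process", "process", base_t["process"], "{base}{model}/{row_id}/process"),
        NodePattern(
            "output",
            "output_entity",
            base_t["information-entity"],
            "{base}{model}/{row_id}/output",
        ),
        NodePattern(
            "attribute",
            "attribute",
            base_t["attribute"],
            "{base}person/{pid}/attr/{model}-output",
        ),
    )
    edges = (
        Edge("role", rel["role-of"], "person"),
        Edge("role", rel["participates-in"], "process"),
        Edge("identifier", rel["denotes"], "role"),
        Edge("process", rel["has-output"], "output"),
        Edge("person", rel["has-attribute"], "attribute"),
        Edge("output", rel["refers-to"], "attribute"),
    )
    literal_slots = (
        LiteralSlotPattern(
            "identifier", rel["has-value"], "pid", _XSD_PREFIX + "string", True
        ),
    )
    return GraphPattern(
        pattern_id="core",
        model_name="core",
        nodes=nodes,
        edges=edges,
        literal_slots=literal_slots,
        namespaces=dict(vocab["prefixes"]),
        vocab=vocab,
    )


# ---------------------------------------------------------------------------
# Specialization


def specialize(
    pattern: GraphPattern,
    template: ModelTemplate,
    *,
    base_iri: str = DEFAULT_BASE_IRI,
) -> GraphPattern:
    """Bind the core pattern to one model template.

    Replaces the generic output node by one node per declared output slot
    (with fixed and per-row specific types and literal slots), mints one
    attribute node per attribute-bearing output, and — for models connected
    to the disease-progression container — adds a part-of edge from every
    output into the container node keyed by (pid, progression_id).
    """
    vocab = pattern.vocab or load_vocabulary()
    rel = vocab["relations"]
    base_t = vocab["base_types"]
    columns = {c.name for c in template.column_specs}

    def check_column(column: Optional[str], context: str) -> None:
        if column is not None and column not in columns:
            raise PatternError(
                f"model {template.model_name}: {context} references column "
                f"{column!r} absent from column_specs"
            )

    check_column(template.process_type_column, "process type")

    nodes = [n for n in pattern.nodes if n.node_id not in ("output", "attribute")]
    # Process: may be specialized by fixed type or by column (assessment tool).
    nodes = [
        replace(
            n,
            specific_type=template.process_type,
            type_column=template.process_type_column,
        )
        if n.node_id == "process"
        else n
        for n in nodes
    ]
    edges = [e for e in pattern.edges if "output" not in (e.subject, e.object)
             and "attribute" not in (e.subject, e.object)]
    literal_slots = [s for s in pattern.literal_slots if s.node != "output"]

    linked = "disease_progression" in template.links_to
    if linked:
        check_column("progression_id", "container link")
        nodes.append(
            NodePattern(
                "container",
                "output_entity",
                base_t["collection"],
                "{base}progression/{pid}/{col:progression_id}",
            )
        )

    for slot in template.outputs:
        check_column(slot.type_column, f"output {slot.name!r}")
        check_column(slot.presence_column, f"output {slot.name!r}")
        node_id = f"output:{slot.name}"
        if slot.container:
            iri_rule = "{base}progression/{pid}/{col:progression_id}"
        else:
            iri_rule = "{base}{model}/{row_id}/output-" + slot.name
            if slot.presence_column:
                iri_rule += "/{col:" + slot.presence_column + "}"
        nodes.append(
            NodePattern(
                node_id,
                "output_entity",
                base_t["collection"] if slot.container
                else base_t["information-entity"],
                iri_rule,
                specific_type=slot.fixed_type,
                type_column=slot.type_column,
            )
        )
        edges.append(Edge("process", rel["has-output"], node_id))
        if slot.attribute:
            attr_id = f"attribute:{slot.name}"
            nodes.append(
                NodePattern(
                    attr_id,
                    "attribute",
                    base_t["attribute"],
                    "{base}person/{pid}/attr/{model}-" + slot.name,
                )
            )
            edges.append(Edge("person", rel["has-attribute"], attr_id))
            edges.append(Edge(node_id, rel["refers-to"], attr_id))
        if linked and not slot.container:
            edges.append(Edge(node_id, rel["part-of"], "container"))
        for lit in slot.literals:
            check_column(lit.column, f"output {slot.name!r} literal")
            literal_slots.append(
                LiteralSlotPattern(
                    node_id,
                    rel["has-value"],
                    lit.column,
                    _xsd_iri(lit.datatype),
                    lit.required,
                )
            )

    namespaces = dict(pattern.namespaces)
    namespaces.setdefault("reg", base_iri)
    return GraphPattern(
        pattern_id=f"cde:{template.model_name}",
        model_name=template.model_name,
        nodes=tuple(nodes),
        edges=tuple(edges),
        literal_slots=tuple(literal_slots),
        namespaces=namespaces,
        vocab=vocab,
    )


# ---------------------------------------------------------------------------
# Extensions beyond the CDEs (lab measurements, PROMs, body measurements)


def _add_process_link(
    pattern: GraphPattern,
    node_id: str,
    relation_slot: str,
    column: str,
    base_type: str,
    value_parent: Optional[str] = None,
) -> GraphPattern:
    vocab = pattern.vocab or load_vocabulary()
    node = NodePattern(
        node_id,
        "output_entity",
        base_type,
        f"@col:{column}",
        value_parent=value_parent,
    )
    edge = Edge("process", vocab["relations"][relation_slot], node_id)
    return replace(pattern, nodes=pattern.nodes + (node,), edges=pattern.edges + (edge,))


def extend_lab_measurement(
    pattern: GraphPattern, input_parent: str, target_parent: str
) -> GraphPattern:
    """Lab-measurement variant: three new connections on the process node.

    An input (constrained to descendants of ``input_parent``, e.g. body
    tissues), a target molecule (descendants of ``target_parent``, e.g.
    measured compounds) and a link to the protocol document.  The rest of
    the pattern is structurally identical to what it extends.
    """
    vocab = pattern.vocab or load_vocabulary()
    ice = vocab["base_types"]["information-entity"]
    pattern = _add_process_link(
        pattern, "lab_input", "has-input", "input_uri", input_parent, input_parent
    )
    pattern = _add_process_link(
        pattern, "lab_target", "has-target", "target_uri", target_parent, target_parent
    )
    return _add_process_link(pattern, "lab_protocol", "has-protocol", "protocol_uri", ice)


def extend_prom(pattern: GraphPattern) -> GraphPattern:
    """Patient-reported outcome variant: the questionnaire item becomes a
    process input (one new process-anchored edge)."""
    vocab = pattern.vocab or load_vocabulary()
    ice = vocab["base_types"]["information-entity"]
    return _add_process_link(pattern, "prom_question", "has-input", "question_uri", ice)


def extend_body_measurement(pattern: GraphPattern) -> GraphPattern:
    """Body-measurement variant: only an additional link from the process to
    the measurement protocol."""
    vocab = pattern.vocab or load_vocabulary()
    ice = vocab["base_types"]["information-entity"]
    return _add_process_link(pattern, "bm_protocol", "has-protocol", "protocol_uri", ice)


# ---------------------------------------------------------------------------
# Instantiation


_PLACEHOLDER_RE = re.compile(r"\{([^}]+)\}")


def _resolve_iri(
    rule: str, row: RowRecord, model: str, base_iri: str
) -> Optional[str]:
    """Resolve an IRI rule for one row; None means the node is absent."""
    if rule.startswith("@col:"):
        column = rule[5:]
        if column not in row.cells:
            raise InstantiationError(f"row {row.row_id}: no column {column!r}")
        value = row.cells[column]
        return value or None

    absent = False

    def substitute(match: re.Match) -> str:
        nonlocal absent
        name = match.group(1)
        if name == "base":
            return base_iri
        if name == "model":
            return model
        if name == "pid":
            value = row.pseudonym
        elif name == "row_id":
            value = row.row_id
        elif name.startswith("col:"):
            column = name[4:]
            if column not in row.cells:
                raise InstantiationError(
                    f"row {row.row_id}: no column {column!r} for slot {name!r}"
                )
            value = row.cells[column]
        else:
            raise InstantiationError(f"unresolvable placeholder {name!r}")
        if not value:
            absent = True
            return ""
        return quote(value, safe="")

    iri = _PLACEHOLDER_RE.sub(substitute, rule)
    return None if absent else iri


def instantiate(
    pattern: GraphPattern,
    row: RowRecord,
    *,
    base_iri: str = DEFAULT_BASE_IRI,
) -> TripleSet:
    """Expand the pattern for a single row into a deterministic TripleSet.

    Node IRIs are pure functions of (base IRI, model, pid/row_id, slot), so
    re-instantiating the same row yields a bit-identical result.  Nodes
    whose IRI rule references an empty cell are absent, along with their
    edges and literal slots; empty optional cells produce no triples.
    """
    if not row.pseudonym:
        raise InstantiationError(f"row {row.row_id}: empty pseudonym")
    if not row.row_id:
        raise InstantiationError("row with empty row_id")
    model = pattern.model_name
    iris: dict[str, Optional[str]] = {}
    triples = set()
    for node in pattern.nodes:
        iri = _resolve_iri(node.iri_rule, row, model, base_iri)
        iris[node.node_id] = iri
        if iri is None:
            continue
        triples.add((iri, RDF_TYPE, node.base_type_iri))
        if node.specific_type:
            triples.add((iri, RDF_TYPE, node.specific_type))
        if node.type_column:
            if node.type_column not in row.cells:
                raise InstantiationError(
                    f"row {row.row_id}: no column {node.type_column!r}"
                )
            value = row.cells[node.type_column]
            if value:
                triples.add((iri, RDF_TYPE, value))
    for edge in pattern.edges:
        s, o = iris.get(edge.subject), iris.get(edge.object)
        if s is not None and o is not None:
            triples.add((s, edge.predicate, o))
    for slot in pattern.literal_slots:
        subject = iris.get(slot.node)
        if subject is None:
            continue
        if slot.column == "pid":
            value = row.pseudonym
        elif slot.column == "row_id":
            value = row.row_id
        else:
            if slot.column not in row.cells:
                raise InstantiationError(
                    f"row {row.row_id}: no column {slot.column!r} for literal slot"
                )
            value = row.cells[slot.column]
        if value:
            triples.add((subject, slot.property, Literal(value, slot.datatype)))
    return TripleSet(frozenset(triples), dict(pattern.namespaces))


def transform_table(
    template: ModelTemplate,
    table: CsvTable,
    *,
    base_iri: str = DEFAULT_BASE_IRI,
    vocab: Optional[Mapping] = None,
) -> TripleSet:
    """Transform a whole (validated) table: union of per-row instantiations."""
    pattern = specialize(build_core_pattern(vocab), template, base_iri=base_iri)
    triples: set = set()
    namespaces = dict(pattern.namespaces)
    for row in table.rows:
        try:
            ts = instantiate(pattern, row, base_iri=base_iri)
        except InstantiationError as exc:
            raise InstantiationError(f"row {row.row_id!r}: {exc}") from exc
        triples |= ts.triples
    return TripleSet(frozenset(triples), namespaces)
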