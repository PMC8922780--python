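"""Generated ShEx schemas and a validator for the emitted CDE graphs.

One schema is generated per model, mirroring the specialized graph pattern:
every node kind gets a shape anchored to its ontological type, required
edges get cardinality 1..1 (1..* where a node legitimately accumulates the
edge across rows, e.g. a role participating in many recording processes),
optional literal slots 0..1.  Conditionally required literals — the death
date, required iff the status value is the "Dead" binding — are encoded as
two alternative shapes discriminated by rdf:type, since the generated
subset deliberately avoids conditional constraints.

The validation engine implements exactly the subset the generator emits:
typed focus-node selection, conjunctive triple constraints with
filter-then-count semantics, value sets, datatypes (with lexical checks),
and one-level shape references.  Schemas are tree-shaped by construction,
so no recursion is needed.  Serialization uses the ShExC compact syntax.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

from .catalog import ModelTemplate, ValueSet
from .csv_template import validate_date
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
    "ConformanceReport",
    "Datatype",
    "IriKind",
    "Shape",
    "ShapeRef",
    "ShapeSchema",
    "TripleConstraint",
    "ValueSetConstraint",
    "generate_shape",
    "parse_shexc",
    "serialize_shexc",
    "validate_graph",
]

_XSD = "http://www.w3.org/2001/XMLSchema#"
UNBOUNDED = -1


@dataclass(frozen=True)
class Datatype:
    datatype: str


@dataclass(frozen=True)
class ValueSetConstraint:
    values: tuple[str, ...]


@dataclass(frozen=True)
class ShapeRef:
    label: str


@dataclass(frozen=True)
class IriKind:
    pass


ValueConstraint = Union[Datatype, ValueSetConstraint, ShapeRef, IriKind]


@dataclass(frozen=True)
class TripleConstraint:
    predicate: str
    constraint: ValueConstraint
    min: int = 1
    max: int = 1  # UNBOUNDED for *

    def __post_init__(self) -> None:
        if self.max != UNBOUNDED and self.min > self.max:
            raise ValueError("min must be <= max")


@dataclass(frozen=True)
class Shape:
    """A shape plus its focus-selection rule.

    Focus nodes are those carrying ``focus_type`` (and ``also_typed`` /
    lacking ``not_typed`` for conditional alternatives).
    """

    label: str
    focus_type: str
    triple_constraints: tuple[TripleConstraint, ...] = ()
    also_typed: Optional[str] = None
    not_typed: Optional[str] = None


@dataclass(frozen=True)
class ShapeSchema:
    model_name: str
    shapes: tuple[Shape, ...]
    start_shape: str
    prefixes: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        labels = {s.label for s in self.shapes}
        referenced = {
            tc.constraint.label
            for s in self.shapes
            for tc in s.triple_constraints
            if isinstance(tc.constraint, ShapeRef)
        }
        undefined = (referenced | {self.start_shape}) - labels
        if undefined:
            raise ValueError(f"undefined shape labels: {sorted(undefined)}")

    def shape(self, label: str) -> Shape:
        for s in self.shapes:
            if s.label == label:
                return s
        raise KeyError(label)


# ---------------------------------------------------------------------------
# Generation


def generate_shape(
    template: ModelTemplate,
    *,
    base_iri: str = DEFAULT_BASE_IRI,
    pattern: Optional[GraphPattern] = None,
) -> ShapeSchema:
    """Generate the ShEx schema mirroring one model's specialized pattern."""
    if pattern is None:
        pattern = specialize(build_core_pattern(), template, base_iri=base_iri)
    vocab = pattern.vocab
    rel = vocab["relations"]
    model = template.model_name

    def label_for(node_id: str) -> str:
        return f"{model}__{node_id.replace(':', '_')}"

    has_attribute_nodes = any(n.kind == "attribute" for n in pattern.nodes)
    attr_label = f"{model}__attribute"
    shapes: list[Shape] = []
    if has_attribute_nodes:
        attr_type = next(
            n.base_type_iri for n in pattern.nodes if n.kind == "attribute"
        )
        shapes.append(Shape(attr_label, attr_type))

    container_node = next(
        (n for n in pattern.nodes if n.node_id == "container"), None
    )
    if container_node is not None:
        shapes.append(Shape(label_for("container"), container_node.base_type_iri))

    outputs_by_node = {f"output:{o.name}": o for o in template.outputs}

    for node in pattern.nodes:
        if node.kind == "attribute" or node.node_id == "container":
            continue
        constraints: list[TripleConstraint] = []
        if node.node_id == "person":
            if has_attribute_nodes:
                constraints.append(
                    TripleConstraint(
                        rel["has-attribute"], ShapeRef(attr_label), 1, UNBOUNDED
                    )
                )
            shapes.append(Shape(label_for("person"), node.base_type_iri,
                                tuple(constraints)))
        elif node.node_id == "role":
            constraints = [
                TripleConstraint(rel["role-of"], ShapeRef(label_for("person")), 1, 1),
                TripleConstraint(
                    rel["participates-in"], ShapeRef(label_for("process")), 1, UNBOUNDED
                ),
            ]
            shapes.append(Shape(label_for("role"), node.base_type_iri, tuple(constraints)))
        elif node.node_id == "identifier":
            constraints = [
                TripleConstraint(rel["denotes"], ShapeRef(label_for("role")), 1, 1),
                TripleConstraint(rel["has-value"], Datatype(_XSD + "string"), 1, 1),
            ]
            shapes.append(
                Shape(label_for("identifier"), node.base_type_iri, tuple(constraints))
            )
        elif node.node_id == "process":
            for out_id, slot in outputs_by_node.items():
                optional = slot.presence_column is not None
                constraints.append(
                    TripleConstraint(
                        rel["has-output"],
                        ShapeRef(label_for(out_id)),
                        0 if optional else 1,
                        1,
                    )
                )
            shapes.append(
                Shape(label_for("process"), node.base_type_iri, tuple(constraints))
            )
        elif node.node_id in outputs_by_node:
            slot = outputs_by_node[node.node_id]
            base_constraints: list[TripleConstraint] = []
            if slot.type_column is not None:
                spec = template.column(slot.type_column)
                if isinstance(spec.constraint, ValueSet):
                    required_type = spec.required and slot.presence_column is None
                    base_constraints.append(
                        TripleConstraint(
                            RDF_TYPE,
                            ValueSetConstraint(spec.constraint.values),
                            1 if required_type else 0,
                            1,
                        )
                    )
            if slot.attribute:
                base_constraints.append(
                    TripleConstraint(rel["refers-to"], ShapeRef(attr_label), 1, 1)
                )
            if container_node is not None and not slot.container:
                base_constraints.append(
                    TripleConstraint(
                        rel["part-of"], ShapeRef(label_for("container")), 1, 1
                    )
                )
            literal_constraints = {
                lit.column: TripleConstraint(
                    rel["has-value"],
                    Datatype(_dt_iri(lit.datatype)),
                    1 if lit.required else 0,
                    1,
                )
                for lit in slot.literals
            }
            cond = template.conditional
            if cond is not None and cond.output == slot.name:
                # Two alternatives discriminated by the controlled type value.
                when_iri = _binding_iri(template, cond)
                dead_literals = dict(literal_constraints)
                dead_literals[cond.require_literal] = TripleConstraint(
                    rel["has-value"],
                    dead_literals[cond.require_literal].constraint,
                    1,
                    1,
                )
                other_literals = dict(literal_constraints)
                other_literals[cond.require_literal] = TripleConstraint(
                    rel["has-value"],
                    other_literals[cond.require_literal].constraint,
                    0,
                    0,
                )
                shapes.append(
                    Shape(
                        label_for(node.node_id) + "__when",
                        slot.fixed_type,
                        tuple(base_constraints) + tuple(dead_literals.values()),
                        also_typed=when_iri,
                    )
                )
                shapes.append(
                    Shape(
                        label_for(node.node_id),
                        slot.fixed_type,
                        tuple(base_constraints) + tuple(other_literals.values()),
                        not_typed=when_iri,
                    )
                )
            else:
                shapes.append(
                    Shape(
                        label_for(node.node_id),
                        slot.fixed_type,
                        tuple(base_constraints) + tuple(literal_constraints.values()),
                    )
                )
        # extension nodes (lab inputs etc.) get no dedicated shape

    return ShapeSchema(
        model_name=model,
        shapes=tuple(shapes),
        start_shape=label_for("process"),
        prefixes=dict(pattern.namespaces),
    )


def _dt_iri(curie_or_iri: str) -> str:
    if curie_or_iri.startswith("xsd:"):
        return _XSD + curie_or_iri[4:]
    return curie_or_iri


def _binding_iri(template: ModelTemplate, cond) -> str:
    spec = template.column(
        next(o.type_column for o in template.outputs if o.name == cond.output)
    )
    if not isinstance(spec.constraint, ValueSet):
        raise ValueError("conditional rule requires a value-set column")
    # The bindings file orders labels as the element definition does; the
    # ValueSet preserves that order, so look the label up via the catalogue
    # ordering exposed on the constraint.
    from .catalog import load_catalog  # local import to avoid cycle at import time

    if spec.constraint.element_id is None:
        raise ValueError("conditional rule requires an element-bound value set")
    catalog = load_catalog()
    return catalog.binding(cond.element_id, cond.when_label)


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class FocusResult:
    node: str
    shape: str
    conforms: bool
    reason: Optional[str] = None


@dataclass(frozen=True)
class ConformanceReport:
    results: tuple[FocusResult, ...]
    summary: Mapping[str, int]

    @property
    def conforms(self) -> bool:
        return self.summary["nonconforming"] == 0

    def nonconforming(self) -> tuple[FocusResult, ...]:
        return tuple(r for r in self.results if not r.conforms)

    def to_json(self) -> str:
        return json.dumps(
            {
                "summary": dict(self.summary),
                "results": [
                    {
                        "node": r.node,
                        "shape": r.shape,
                        "conforms": r.conforms,
                        **({"reason": r.reason} if r.reason else {}),
                    }
                    for r in self.results
                ],
            },
            indent=2,
        )


def _literal_lexically_valid(literal: Literal) -> bool:
    dt = literal.datatype
    if dt == _XSD + "date":
        return validate_date(literal.lexical)
    if dt == _XSD + "decimal":
        return re.fullmatch(r"[+-]?(\d+(\.\d*)?|\.\d+)", literal.lexical) is not None
    if dt == _XSD + "integer":
        return re.fullmatch(r"[+-]?\d+", literal.lexical) is not None
    if dt == _XSD + "gYear":
        return re.fullmatch(r"\d{4}", literal.lexical) is not None
    return True


def validate_graph(schema: ShapeSchema, ts: TripleSet) -> ConformanceReport:
    """Judge every focus node of every shape in the schema.

    Focus nodes are selected by rdf:type against each shape's anchor type;
    a valid transformation output conforms for 100% of focus nodes, and an
    empty graph yields an empty report.
    """
    types: dict[str, set[str]] = {}
    objects: dict[tuple[str, str], list] = {}
    for s, p, o in ts.triples:
        if p == RDF_TYPE and isinstance(o, str):
            types.setdefault(s, set()).add(o)
        objects.setdefault((s, p), []).append(o)

    def matches(value, constraint: ValueConstraint) -> bool:
        if isinstance(constraint, Datatype):
            return (
                isinstance(value, Literal)
                and value.datatype == constraint.datatype
                and _literal_lexically_valid(value)
            )
        if isinstance(constraint, ValueSetConstraint):
            return isinstance(value, str) and value in constraint.values
        if isinstance(constraint, ShapeRef):
            referred = schema.shape(constraint.label)
            return isinstance(value, str) and referred.focus_type in types.get(
                value, set()
            )
        return isinstance(value, str)  # IriKind

    results: list[FocusResult] = []
    for shape in schema.shapes:
        for node, node_types in sorted(types.items()):
            if shape.focus_type not in node_types:
                continue
            if shape.also_typed is not None and shape.also_typed not in node_types:
                continue
            if shape.not_typed is not None and shape.not_typed in node_types:
                continue
            reason = None
            for tc in shape.triple_constraints:
                count = sum(
                    1 for o in objects.get((node, tc.predicate), ()) if matches(o, tc.constraint)
                )
                if count < tc.min or (tc.max != UNBOUNDED and count > tc.max):
                    upper = "*" if tc.max == UNBOUNDED else str(tc.max)
                    reason = (
                        f"cardinality violation on <{tc.predicate}>: found "
                        f"{count} matching value(s), expected {tc.min}..{upper}"
                    )
                    break
            results.append(FocusResult(node, shape.label, reason is None, reason))
    conforming = sum(1 for r in results if r.conforms)
    return ConformanceReport(
        results=tuple(results),
        summary={
            "focus_nodes": len(results),
            "conforming": conforming,
            "nonconforming": len(results) - conforming,
        },
    )


# ---------------------------------------------------------------------------
# ShExC compact syntax


def _card_suffix(tc: TripleConstraint) -> str:
    if (tc.min, tc.max) == (1, 1):
        return ""
    if (tc.min, tc.max) == (0, 1):
        return " ?"
    if (tc.min, tc.max) == (1, UNBOUNDED):
        return " +"
    if (tc.min, tc.max) == (0, UNBOUNDED):
        return " *"
    upper = "" if tc.max == UNBOUNDED else str(tc.max)
    return " {%d,%s}" % (tc.min, upper)


def serialize_shexc(schema: ShapeSchema) -> str:
    """Render the schema in ShEx compact syntax (one shape per label)."""
    lines = []
    for prefix, iri in schema.prefixes.items():
        lines.append(f"PREFIX {prefix}: <{iri}>")
    lines.append("")
    lines.append(f"start = @<{schema.start_shape}>")
    lines.append("")
    for shape in schema.shapes:
        lines.append(f"<{shape.label}> {{")
        entries = []
        anchor = [f"<{shape.focus_type}>"]
        if shape.also_typed:
            anchor.append(f"<{shape.also_typed}>")
        entries.append(f"  a [{' '.join(anchor)}] +")
        if shape.not_typed:
            entries.append(f"  a [- <{shape.not_typed}>] *")
        for tc in shape.triple_constraints:
            c = tc.constraint
            if isinstance(c, Datatype):
                value = f"<{c.datatype}>"
            elif isinstance(c, ValueSetConstraint):
                value = "[" + " ".join(f"<{v}>" for v in c.values) + "]"
            elif isinstance(c, ShapeRef):
                value = f"@<{c.label}>"
            else:
                value = "IRI"
            entries.append(f"  <{tc.predicate}> {value}{_card_suffix(tc)}")
        lines.append(" ;\n".join(entries))
        lines.append("}")
        lines.append("")
    return "\n".join(lines)


# Shape bodies end with a closing brace on its own line, which keeps inner
# cardinality braces ({m,n}) out of the match.
_SHAPE_RE = re.compile(r"<([^>]+)>\s*\{(.*?)^\}", re.DOTALL | re.MULTILINE)
_START_RE = re.compile(r"^start\s*=\s*@<([^>]+)>\s*$", re.MULTILINE)
_PREFIX_RE = re.compile(r"^PREFIX\s+([\w-]*):\s+<([^>]+)>\s*$", re.MULTILINE)
_CONSTRAINT_RE = re.compile(
    r"^(a|<[^>]+>)\s+(\[[^\]]*\]|@<[^>]+>|<[^>]+>|IRI)\s*(\?|\+|\*|\{\d+,\d*\})?$"
)


def parse_shexc(text: str) -> dict:
    """Parse the ShExC subset emitted by serialize_shexc.

    Returns ``{"start": label, "prefixes": {...}, "shapes": {label:
    [(predicate, value, min, max), ...]}}``.  Raises ValueError on text that
    does not follow the compact-syntax grammar subset, so it doubles as a
    well-formedness check in tests.
    """
    start_match = _START_RE.search(text)
    if not start_match:
        raise ValueError("no start shape declaration")
    prefixes = dict(_PREFIX_RE.findall(text))
    body = _START_RE.sub("", _PREFIX_RE.sub("", text))
    shapes: dict[str, list] = {}
    consumed_spans = []
    for match in _SHAPE_RE.finditer(body):
        label, content = match.group(1), match.group(2)
        consumed_spans.append(match.span())
        constraints = []
        for raw in content.split(";"):
            raw = " ".join(raw.split())
            if not raw:
                continue
            m = _CONSTRAINT_RE.match(raw)
            if not m:
                raise ValueError(f"shape <{label}>: bad constraint {raw!r}")
            predicate = m.group(1)
            card = m.group(3) or ""
            if card == "?":
                lo, hi = 0, 1
            elif card == "+":
                lo, hi = 1, UNBOUNDED
            elif card == "*":
                lo, hi = 0, UNBOUNDED
            elif card.startswith("{"):
                lo_s, hi_s = card[1:-1].split(",")
                lo, hi = int(lo_s), int(hi_s) if hi_s else UNBOUNDED
            else:
                lo, hi = 1, 1
            constraints.append((predicate, m.group(2), lo, hi))
        shapes[label] = constraints
    leftover = _SHAPE_RE.sub("", body).strip()
    if leftover:
        raise ValueError(f"unparseable ShExC content: {leftover[:80]!r}")
    return {"start": start_match.group(1), "prefixes": prefixes, "shapes": shapes}
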