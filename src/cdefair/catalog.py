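"""Machine-readable catalogue of the EU RD Platform common data elements.

The catalogue bundles the 16 common data elements (CDEs) that every rare
disease registry is expected to export, and the 11 semantic model templates
that cover them.  Each template fixes the per-model CSV contract (column
names, datatypes, constraints) and the hooks the graph builder needs
(output slots, literal slots, container links).  Controlled labels are bound
to ontology IRIs through an overridable bindings file: the labels are part
of the element definitions, the IRIs are configuration.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import yaml

__all__ = [
    "CDEDefinition",
    "Catalog",
    "CatalogConfigError",
    "ColumnSpec",
    "ConditionalRule",
    "ControlledValue",
    "DescendantOf",
    "LiteralSlot",
    "ModelTemplate",
    "OutputSlot",
    "Regex",
    "UnknownElementError",
    "UnknownModelError",
    "ValueSet",
    "load_catalog",
]

MODEL_NAMES = (
    "disease_progression",
    "care_pathway",
    "diagnosis",
    "disease_history",
    "genetic_diagnosis",
    "patient_consent",
    "patient_status",
    "personal_information",
    "phenotyping",
    "disability",
    "undiagnosed",
)

_ELEMENT_ID_RE = re.compile(r"^\d\.\d$")
_ABSOLUTE_IRI_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.-]*://\S+$|^urn:\S+$")


class CatalogConfigError(ValueError):
    """Raised when the bundled data or an override file is malformed."""


class UnknownModelError(KeyError):
    """Raised when a model name is not in the catalogue."""


class UnknownElementError(KeyError):
    """Raised when an element id is not in the catalogue."""


@dataclass(frozen=True)
class ControlledValue:
    """A controlled label together with its configured ontology IRI."""

    label: str
    term_iri: str

    def __post_init__(self) -> None:
        if not _ABSOLUTE_IRI_RE.match(self.term_iri):
            raise CatalogConfigError(
                f"binding for label {self.label!r} is not an absolute IRI: "
                f"{self.term_iri!r}"
            )


@dataclass(frozen=True)
class CDEDefinition:
    """One of the 16 common data elements."""

    element_id: str
    name: str
    value_kind: str
    allowed_values: tuple[ControlledValue, ...] = ()
    parent_class_iri: Optional[str] = None

    VALUE_KINDS = frozenset(
        {
            "free_string",
            "iso_date",
            "controlled_term",
            "ontology_class_constrained",
            "boolean_yes_no",
            "url_or_no",
            "numeric_score",
        }
    )

    def __post_init__(self) -> None:
        if not _ELEMENT_ID_RE.match(self.element_id):
            raise CatalogConfigError(f"bad element id {self.element_id!r}")
        if self.value_kind not in self.VALUE_KINDS:
            raise CatalogConfigError(f"bad value kind {self.value_kind!r}")
        has_values = self.value_kind in ("controlled_term", "boolean_yes_no")
        if has_values != bool(self.allowed_values):
            raise CatalogConfigError(
                f"element {self.element_id}: allowed_values must be "
                f"non-empty iff value kind is controlled_term/boolean_yes_no"
            )


# ---------------------------------------------------------------------------
# Column constraints


@dataclass(frozen=True)
class Regex:
    pattern: str

    def matches(self, value: str) -> bool:
        return re.fullmatch(self.pattern, value) is not None


@dataclass(frozen=True)
class ValueSet:
    values: tuple[str, ...]
    element_id: Optional[str] = None  # provenance, for error messages


@dataclass(frozen=True)
class DescendantOf:
    parent_iri: str


Constraint = Union[None, Regex, ValueSet, DescendantOf]


@dataclass(frozen=True)
class ColumnSpec:
    """Contract for one CSV column of a model template."""

    name: str
    datatype: str  # string | iso_date | iri | decimal | integer
    required: bool = True
    constraint: Constraint = None

    DATATYPES = frozenset({"string", "iso_date", "iri", "decimal", "integer"})

    def __post_init__(self) -> None:
        if self.datatype not in self.DATATYPES:
            raise CatalogConfigError(
                f"column {self.name!r}: bad datatype {self.datatype!r}"
            )
        if isinstance(self.constraint, DescendantOf) and self.datatype != "iri":
            raise CatalogConfigError(
                f"column {self.name!r}: descendant_of requires datatype iri"
            )


@dataclass(frozen=True)
class LiteralSlot:
    """A column that becomes a typed literal on an output node."""

    column: str
    datatype: str  # xsd CURIE, e.g. "xsd:date"
    required: bool = False


@dataclass(frozen=True)
class OutputSlot:
    """One information-content output of the model's clinical process."""

    name: str
    fixed_type: str
    type_column: Optional[str] = None
    presence_column: Optional[str] = None
    attribute: bool = True
    container: bool = False
    literals: tuple[LiteralSlot, ...] = ()


@dataclass(frozen=True)
class ConditionalRule:
    """A literal that is required only for one controlled output type.

    E.g. the death date is required iff the status value is the binding of
    the "Dead" label.
    """

    output: str
    element_id: str
    when_label: str
    require_literal: str


@dataclass(frozen=True)
class ModelTemplate:
    """One of the 11 semantic CDE model templates."""

    model_name: str
    purpose: str
    covered_element_ids: tuple[str, ...]
    column_specs: tuple[ColumnSpec, ...]
    outputs: tuple[OutputSlot, ...]
    links_to: tuple[str, ...] = ()
    process_type: Optional[str] = None
    process_type_column: Optional[str] = None
    conditional: Optional[ConditionalRule] = None
    at_least_one_of: tuple[tuple[str, ...], ...] = ()
    pattern_id: str = ""

    def __post_init__(self) -> None:
        names = [c.name for c in self.column_specs]
        if len(set(names)) != len(names):
            raise CatalogConfigError(
                f"model {self.model_name}: duplicate column names"
            )
        if "pid" not in names:
            raise CatalogConfigError(
                f"model {self.model_name}: every model carries the pseudonym "
                f"column 'pid'"
            )
        if not self.pattern_id:
            object.__setattr__(self, "pattern_id", f"cde:{self.model_name}")

    def column(self, name: str) -> ColumnSpec:
        for spec in self.column_specs:
            if spec.name == name:
                return spec
        raise KeyError(name)

    @property
    def required_columns(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.column_specs if c.required)


def _normalize_name(name: str) -> str:
    return re.sub(r"[\s\-]+", "_", name.strip().lower())


@dataclass(frozen=True)
class Catalog:
    """The loaded element definitions, model templates and bindings."""

    elements: Mapping[str, CDEDefinition]
    models: Mapping[str, ModelTemplate]
    bindings: Mapping[str, Mapping[str, str]]  # element_id -> label -> IRI

    def get_model(self, name: str) -> ModelTemplate:
        """Look up a template by name (case/separator insensitive)."""
        key = _normalize_name(name)
        try:
            return self.models[key]
        except KeyError:
            raise UnknownModelError(
                f"unknown model {name!r}; available: "
                + ", ".join(sorted(self.models))
            ) from None

    def get_element(self, element_id: str) -> CDEDefinition:
        try:
            return self.elements[element_id]
        except KeyError:
            raise UnknownElementError(
                f"unknown element id {element_id!r}; available: "
                + ", ".join(sorted(self.elements))
            ) from None

    def models_for_element(self, element_id: str) -> list[str]:
        """All model names whose template covers the given element."""
        self.get_element(element_id)  # raises for unknown ids
        return [
            name
            for name, tpl in self.models.items()
            if element_id in tpl.covered_element_ids
        ]

    def binding(self, element_id: str, label: str) -> str:
        try:
            return self.bindings[element_id][label]
        except KeyError:
            raise CatalogConfigError(
                f"no binding for element {element_id!r} label {label!r}"
            ) from None


# ---------------------------------------------------------------------------
# Loading


def _data_text(relative: str) -> str:
    return (resources.files("cdefair") / "data" / relative).read_text("utf-8")


def _merge_binding_overrides(
    base: dict[str, dict[str, str]], overrides: object
) -> dict[str, dict[str, str]]:
    if not isinstance(overrides, dict):
        raise CatalogConfigError("'bindings' override must be a mapping")
    merged = {eid: dict(labels) for eid, labels in base.items()}
    for eid, labels in overrides.items():
        if eid not in merged:
            raise CatalogConfigError(f"bindings override: unknown element {eid!r}")
        if not isinstance(labels, dict):
            raise CatalogConfigError(
                f"bindings override for element {eid!r} must be a mapping"
            )
        for label, iri in labels.items():
            if label not in merged[eid]:
                raise CatalogConfigError(
                    f"bindings override: unknown label {label!r} for element "
                    f"{eid!r}"
                )
            if not isinstance(iri, str) or not _ABSOLUTE_IRI_RE.match(iri):
                raise CatalogConfigError(
                    f"bindings override: value for {eid!r}/{label!r} is not "
                    f"an absolute IRI"
                )
            merged[eid][label] = iri
    return merged


def _parse_constraint(
    raw: object, bindings: Mapping[str, Mapping[str, str]]
) -> Constraint:
    if raw is None or raw == "none":
        return None
    if not isinstance(raw, dict) or len(raw) != 1:
        raise CatalogConfigError(f"bad constraint {raw!r}")
    (kind, arg), = raw.items()
    if kind == "regex":
        return Regex(str(arg))
    if kind == "descendant_of":
        return DescendantOf(str(arg))
    if kind == "value_set_element":
        eid = str(arg)
        if eid not in bindings:
            raise CatalogConfigError(f"no bindings for element {eid!r}")
        return ValueSet(tuple(bindings[eid].values()), element_id=eid)
    if kind == "value_set":
        return ValueSet(tuple(str(v) for v in arg))
    raise CatalogConfigError(f"unknown constraint kind {kind!r}")


def _load_model(
    raw: dict, bindings: Mapping[str, Mapping[str, str]]
) -> ModelTemplate:
    columns = tuple(
        ColumnSpec(
            name=c["name"],
            datatype=c["datatype"],
            required=bool(c.get("required", True)),
            constraint=_parse_constraint(c.get("constraint"), bindings),
        )
        for c in raw["columns"]
    )
    outputs = tuple(
        OutputSlot(
            name=o["name"],
            fixed_type=o["fixed_type"],
            type_column=o.get("type_column"),
            presence_column=o.get("presence_column"),
            attribute=bool(o.get("attribute", True)),
            container=bool(o.get("container", False)),
            literals=tuple(
                LiteralSlot(
                    column=l["column"],
                    datatype=l["datatype"],
                    required=bool(l.get("required", False)),
                )
                for l in o.get("literals", ())
            ),
        )
        for o in raw["outputs"]
    )
    cond = None
    if "conditional" in raw:
        c = raw["conditional"]
        cond = ConditionalRule(
            output=c["output"],
            element_id=c["element"],
            when_label=c["when_label"],
            require_literal=c["require_literal"],
        )
    template = ModelTemplate(
        model_name=raw["model_name"],
        purpose=str(raw["purpose"]).strip(),
        covered_element_ids=tuple(raw["covered_element_ids"]),
        column_specs=columns,
        outputs=outputs,
        links_to=tuple(raw.get("links_to", ())),
        process_type=raw.get("process_type"),
        process_type_column=raw.get("process_type_column"),
        conditional=cond,
        at_least_one_of=tuple(
            tuple(group) for group in raw.get("at_least_one_of", ())
        ),
    )
    column_names = {c.name for c in columns}
    for out in outputs:
        referenced = [s.column for s in out.literals]
        if out.type_column:
            referenced.append(out.type_column)
        if out.presence_column:
            referenced.append(out.presence_column)
        missing = [c for c in referenced if c not in column_names]
        if missing:
            raise CatalogConfigError(
                f"model {template.model_name}: output {out.name!r} references "
                f"unknown columns {missing}"
            )
    return template


def load_catalog(
    config_path: Optional[Union[str, Path]] = None,
    *,
    config: Optional[dict] = None,
) -> Catalog:
    """Load the bundled catalogue, optionally applying a config override.

    The override file (YAML) may carry a ``bindings`` section remapping
    controlled-value labels to different term IRIs; element definitions and
    template structure are fixed.  Loading is idempotent.

    Parameters
    ----------
    config_path:
        Path to a YAML override file, or None for the bundled defaults.
    config:
        An already-parsed override mapping (mutually exclusive convenience
        for programmatic use; ``config_path`` wins if both are given).
    """
    bindings_raw = yaml.safe_load(_data_text("bindings.yaml"))
    bindings = {
        str(eid): {str(k): str(v) for k, v in labels.items()}
        for eid, labels in bindings_raw.items()
    }

    if config_path is not None:
        try:
            text = Path(config_path).read_text("utf-8")
        except OSError as exc:
            raise CatalogConfigError(f"cannot read override file: {exc}") from exc
        config = yaml.safe_load(text) or {}
        if not isinstance(config, dict):
            raise CatalogConfigError("override file must hold a YAML mapping")
    if config:
        known = {"bindings", "base_iri", "vocabulary", "privacy"}
        unknown = set(config) - known
        if unknown:
            raise CatalogConfigError(
                f"unknown configuration keys: {sorted(unknown)}"
            )
        if "bindings" in config:
            bindings = _merge_binding_overrides(bindings, config["bindings"])

    elements_raw = yaml.safe_load(_data_text("catalog/elements.yaml"))["elements"]
    elements: dict[str, CDEDefinition] = {}
    for raw in elements_raw:
        eid = str(raw["element_id"])
        labels = raw.get("allowed_labels", ())
        allowed = tuple(
            ControlledValue(label=str(lbl), term_iri=bindings[eid][str(lbl)])
            for lbl in labels
        )
        definition = CDEDefinition(
            element_id=eid,
            name=str(raw["name"]),
            value_kind=str(raw["value_kind"]),
            allowed_values=allowed,
            parent_class_iri=raw.get("parent_class_iri"),
        )
        if eid in elements:
            raise CatalogConfigError(f"duplicate element id {eid!r}")
        elements[eid] = definition

    models: dict[str, ModelTemplate] = {}
    for name in MODEL_NAMES:
        raw = yaml.safe_load(_data_text(f"catalog/models/{name}.yaml"))
        template = _load_model(raw, bindings)
        if template.model_name != name:
            raise CatalogConfigError(
                f"model file {name}.yaml declares {template.model_name!r}"
            )
        models[name] = template

    catalog = Catalog(elements=elements, models=models, bindings=bindings)
    _check_catalog(catalog)
    return catalog


def _check_catalog(catalog: Catalog) -> None:
    if len(catalog.elements) != 16:
        raise CatalogConfigError(
            f"catalogue must define 16 elements, found {len(catalog.elements)}"
        )
    if len(catalog.models) != 11:
        raise CatalogConfigError(
            f"catalogue must define 11 models, found {len(catalog.models)}"
        )
    covered = set()
    for tpl in catalog.models.values():
        covered.update(tpl.covered_element_ids)
    missing = set(catalog.elements) - covered
    if missing:
        raise CatalogConfigError(f"elements not covered by any model: {missing}")
    extra = covered - set(catalog.elements)
    if extra:
        raise CatalogConfigError(f"models cover unknown elements: {extra}")


# Spec'd free functions mirroring the Catalog methods.


def get_model(catalog: Catalog, name: str) -> ModelTemplate:
    return catalog.get_model(name)


def models_for_element(catalog: Catalog, element_id: str) -> list[str]:
    return catalog.models_for_element(element_id)
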