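"""Synthetic multi-file registry exports for testing without downloads.

Generates internally consistent cohorts: pseudonyms are shared across all
model files, clinical dates are ordered (birth < onset <= diagnosis <=
first contact; a death date exists iff the status is Dead and falls after
birth), controlled cells are drawn from the catalogue bindings, and
diagnosis-linked files share progression (episode) identifiers so the
disease-progression container groups them.  Output is deterministic under a
fixed seed.  A companion corruptor injects ledger-tracked violations so
error-detection recall can be measured exactly.

Dates are sampled uniformly within the window and then ordered; the
generator aims at structural plausibility, not demographic realism (no
disease prevalence or survival modelling).
"""

from __future__ import annotations

import datetime as _dt
import random
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

from .catalog import (
    Catalog,
    DescendantOf,
    ModelTemplate,
    Regex,
    ValueSet,
    load_catalog,
)
from .csv_template import (
    ISSUE_CODES,
    CsvTable,
    RowRecord,
    load_term_closures,
    mint_row_id,
    write_csv,
)

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "inject_errors",
    "write_cohort",
]

_VARIANTS = (
    "NM_000492.3:c.1521_1523delCTT",
    "NM_004006.2:c.8713C>T",
    "NM_000138.4:c.3037G>A",
    "NM_002834.4:c.922A>G",
    "NC_000017.11:g.43094464G>A",
)
_GENES = (
    "https://identifiers.org/hgnc/1884",   # CFTR
    "https://identifiers.org/hgnc/2928",   # DMD
    "https://identifiers.org/hgnc/3603",   # FBN1
    "https://identifiers.org/hgnc/9644",   # PTPN11
)

_CLOCK_EPOCH = _dt.datetime(2021, 6, 1, 12, 0, 0)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort."""

    n_patients: int = 100
    seed: int = 0
    model_inclusion: Mapping[str, float] = field(default_factory=dict)
    date_window: tuple[_dt.date, _dt.date] = (
        _dt.date(1950, 1, 1),
        _dt.date(2020, 12, 31),
    )
    error_rate: float = 0.0
    error_kinds: tuple[str, ...] = ISSUE_CODES

    def __post_init__(self) -> None:
        for prob in self.model_inclusion.values():
            if not 0.0 <= prob <= 1.0:
                raise ValueError("inclusion probabilities must be in [0, 1]")
        if self.date_window[0] >= self.date_window[1]:
            raise ValueError("date window min must precede max")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error rate must be in [0, 1]")


def _uniform_date(rng: random.Random, lo: _dt.date, hi: _dt.date) -> _dt.date:
    span = (hi - lo).days
    return lo + _dt.timedelta(days=rng.randint(0, max(span, 0)))


def _labels(catalog: Catalog, element_id: str) -> list[str]:
    return [v.label for v in catalog.get_element(element_id).allowed_values]


def generate_cohort(
    config: CohortConfig, catalog: Optional[Catalog] = None
) -> dict[str, CsvTable]:
    """Generate one CSV table per included model.

    Every included model gets at most one row per patient; whether a given
    patient contributes to a model is Bernoulli per the inclusion
    probability (default 1.0 for all 11 models).  Patients contributing a
    diagnosis row always also contribute disease-history and
    disease-progression rows, preserving cross-file episode integrity.
    """
    catalog = catalog or load_catalog()
    closures = load_term_closures()
    rng = random.Random(config.seed)
    inclusion = {name: 1.0 for name in catalog.models}
    inclusion.update(config.model_inclusion)

    hpo_terms = sorted(
        closures.members("http://purl.obolibrary.org/obo/HP_0000118")
        - {"http://purl.obolibrary.org/obo/HP_0000118"}
    )
    ordo_terms = sorted(
        closures.members("http://www.orpha.net/ORDO/Orphanet_C001")
        - {"http://www.orpha.net/ORDO/Orphanet_C001"}
    )
    tool_terms = sorted(
        closures.members("http://purl.obolibrary.org/obo/NCIT_C20993")
        - {"http://purl.obolibrary.org/obo/NCIT_C20993"}
    )

    lo, hi = config.date_window
    rows: dict[str, list[dict[str, str]]] = {name: [] for name in inclusion}
    sequence = 0

    def next_row_id() -> str:
        nonlocal sequence
        row_id = mint_row_id(_CLOCK_EPOCH, sequence)
        sequence += 1
        return row_id

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        include = {name: rng.random() < prob for name, prob in inclusion.items()}
        if include.get("diagnosis"):
            # Episode integrity: the container and its history must exist.
            for forced in ("disease_history", "disease_progression"):
                if forced in include:
                    include[forced] = True

        birth = _uniform_date(rng, lo, hi - _dt.timedelta(days=365 * 5))
        clinical = sorted(
            _uniform_date(rng, birth + _dt.timedelta(days=1), hi) for _ in range(3)
        )
        onset, diagnosis_date, first_contact = clinical
        status_label = rng.choices(
            _labels(catalog, "3.1"), weights=(80, 10, 5, 5)
        )[0]
        death = (
            _uniform_date(rng, birth + _dt.timedelta(days=1), hi)
            if status_label == "Dead"
            else None
        )
        sex_label = rng.choice(_labels(catalog, "2.2"))
        episode = "E1"

        if include.get("disease_progression"):
            rows["disease_progression"].append(
                {"pid": pid, "row_id": next_row_id(), "progression_id": episode}
            )
        if include.get("care_pathway"):
            rows["care_pathway"].append(
                {
                    "pid": pid,
                    "row_id": next_row_id(),
                    "progression_id": episode,
                    "first_contact_date": first_contact.isoformat(),
                }
            )
        if include.get("diagnosis"):
            rows["diagnosis"].append(
                {
                    "pid": pid,
                    "row_id": next_row_id(),
                    "progression_id": episode,
                    "diagnosis_uri": rng.choice(ordo_terms),
                }
            )
        if include.get("disease_history"):
            onset_as_date = rng.random() < 0.7
            diag_as_date = rng.random() < 0.7
            rows["disease_history"].append(
                {
                    "pid": pid,
                    "row_id": next_row_id(),
                    "progression_id": episode,
                    "onset_category_uri": ""
                    if onset_as_date
                    else catalog.binding("5.1", rng.choice(_labels(catalog, "5.1"))),
                    "onset_date": onset.isoformat() if onset_as_date else "",
                    "diagnosis_category_uri": ""
                    if diag_as_date
                    else catalog.binding("5.2", rng.choice(_labels(catalog, "5.2"))),
                    "diagnosis_date": diagnosis_date.isoformat() if diag_as_date else "",
                }
            )
        if include.get("genetic_diagnosis"):
            rows["genetic_diagnosis"].append(
                {
                    "pid": pid,
                    "row_id": next_row_id(),
                    "progression_id": episode,
                    "variant_hgvs": rng.choice(_VARIANTS),
                    "gene_uri": rng.choice(_GENES) if rng.random() < 0.7 else "",
                }
            )
        if include.get("patient_consent"):
            yes_no = lambda eid: catalog.binding(eid, rng.choice(["Yes", "No"]))
            rows["patient_consent"].append(
                {
                    "pid": pid,
                    "row_id": next_row_id(),
                    "consent_contact_uri": yes_no("7.1"),
                    "consent_reuse_uri": yes_no("7.2"),
                    "sample_available_uri": yes_no("7.3"),
                    "biobank_url": f"https://biobank.example.org/b{rng.randint(1, 20):03d}"
                    if rng.random() < 0.4
                    else "",
                }
            )
        if include.get("patient_status"):
            rows["patient_status"].append(
                {
                    "pid": pid,
                    "row_id": next_row_id(),
                    "status_uri": catalog.binding("3.1", status_label),
                    "death_date": death.isoformat() if death else "",
                }
            )
        if include.get("personal_information"):
            rows["personal_information"].append(
                {
                    "pid": pid,
                    "row_id": next_row_id(),
                    "birth_date": birth.isoformat(),
                    "sex_uri": catalog.binding("2.2", sex_label),
                }
            )
        if include.get("phenotyping"):
            rows["phenotyping"].append(
                {
                    "pid": pid,
                    "row_id": next_row_id(),
                    "phenotype_uri": rng.choice(hpo_terms),
                }
            )
        if include.get("disability"):
            rows["disability"].append(
                {
                    "pid": pid,
                    "row_id": next_row_id(),
                    "tool_uri": rng.choice(tool_terms),
                    "score": f"{rng.uniform(0, 100):.1f}",
                }
            )
        if include.get("undiagnosed"):
            pick = rng.random()
            rows["undiagnosed"].append(
                {
                    "pid": pid,
                    "row_id": next_row_id(),
                    "phenotype_uri": rng.choice(hpo_terms) if pick < 0.8 else "",
                    "variant_hgvs": rng.choice(_VARIANTS) if pick > 0.3 else "",
                }
            )

    tables: dict[str, CsvTable] = {}
    for name, model_rows in rows.items():
        if inclusion.get(name, 0.0) <= 0.0:
            continue
        template = catalog.get_model(name)
        header = tuple(c.name for c in template.column_specs)
        records = tuple(
            RowRecord(row_id=r["row_id"], pseudonym=r["pid"], cells=dict(r))
            for r in model_rows
        )
        tables[name] = CsvTable(model_name=name, header=header, rows=records)
    return tables


def write_cohort(
    tables: Mapping[str, CsvTable], folder: Union[str, Path]
) -> list[Path]:
    """Write one CSV per model into ``folder`` (pipeline discovery naming)."""
    folder = Path(folder)
    folder.mkdir(parents=True, exist_ok=True)
    return [write_csv(table, folder / f"{name}.csv") for name, table in tables.items()]


# ---------------------------------------------------------------------------
# Error injection


def _candidate_columns(template: ModelTemplate, kind: str) -> list[str]:
    cols = template.column_specs
    if kind == "bad_date":
        return [c.name for c in cols if c.datatype == "iso_date"]
    if kind == "bad_iri":
        return [c.name for c in cols if c.datatype == "iri"]
    if kind == "not_in_value_set":
        return [
            c.name for c in cols if isinstance(c.constraint, (ValueSet, Regex))
        ]
    if kind == "not_descendant":
        return [c.name for c in cols if isinstance(c.constraint, DescendantOf)]
    if kind == "missing_required":
        protected = {"row_id"}
        return [c.name for c in cols if c.required and c.name not in protected]
    if kind == "bad_number":
        return [c.name for c in cols if c.datatype in ("decimal", "integer")]
    return []  # duplicate_row_id handled separately


def _corrupt_value(template: ModelTemplate, column: str, kind: str) -> str:
    if kind == "bad_date":
        return "31/12/2020"
    if kind == "bad_iri":
        return "Male"
    if kind == "not_in_value_set":
        if template.column(column).datatype == "iri":
            return "http://example.org/not-a-valid-term"
        return "###invalid###"
    if kind == "not_descendant":
        return "http://purl.obolibrary.org/obo/HP_9999999"
    if kind == "missing_required":
        return ""
    if kind == "bad_number":
        return "12.3.4"
    raise ValueError(kind)


def inject_errors(
    table: CsvTable,
    rate: float,
    kinds: Sequence[str] = ISSUE_CODES,
    seed: int = 0,
    catalog: Optional[Catalog] = None,
) -> tuple[CsvTable, list[tuple[str, str, str]]]:
    """Corrupt a copy of ``table`` and return it with an exact ledger.

    Each row is corrupted with probability ``rate`` by one randomly chosen
    applicable violation kind.  The ledger lists (row_id, column, code) for
    every injected violation; ``validate_table`` on the corrupted table
    reports a superset of the ledger.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    unknown = set(kinds) - set(ISSUE_CODES)
    if unknown:
        raise ValueError(f"unknown issue codes: {sorted(unknown)}")
    catalog = catalog or load_catalog()
    template = catalog.get_model(table.model_name)
    rng = random.Random(seed)
    ledger: list[tuple[str, str, str]] = []
    new_rows = list(table.rows)
    for idx, row in enumerate(table.rows):
        if rng.random() >= rate:
            continue
        applicable = [
            k
            for k in kinds
            if (k == "duplicate_row_id" and idx > 0)
            or (k != "duplicate_row_id" and _candidate_columns(template, k))
        ]
        if not applicable:
            continue
        kind = rng.choice(applicable)
        cells = dict(row.cells)
        if kind == "duplicate_row_id":
            # Copy the (already final) id of the preceding row so the pair is
            # guaranteed to survive any later injections.
            donor = new_rows[idx - 1]
            if donor.row_id == row.row_id:
                continue
            cells["row_id"] = donor.row_id
            new_rows[idx] = replace(row, row_id=donor.row_id, cells=cells)
            ledger.append((donor.row_id, "row_id", kind))
            continue
        column = rng.choice(_candidate_columns(template, kind))
        cells[column] = _corrupt_value(template, column, kind)
        new_row = replace(row, cells=cells)
        if column == "pid":
            new_row = replace(new_row, pseudonym=cells[column])
        new_rows[idx] = new_row
        ledger.append((row.row_id, column, kind))
    return replace(table, rows=tuple(new_rows)), ledger
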