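"""Core pattern structure, specialization, instantiation, serialization."""

import re
from urllib.parse import quote

import pytest
from rdflib import Graph
from rdflib.compare import isomorphic

from cdefair.catalog import CatalogConfigError
from cdefair.csv_template import RowRecord
from cdefair.sio_graph import (
    DEFAULT_BASE_IRI,
    InstantiationError,
    Literal,
    RDF_TYPE,
    TripleSet,
    build_core_pattern,
    extend_body_measurement,
    extend_lab_measurement,
    extend_prom,
    from_rdflib,
    instantiate,
    serialize,
    specialize,
    to_rdflib,
    transform_table,
)

XSD_DATE = "http://www.w3.org/2001/XMLSchema#date"


def _specialized(catalog, name):
    return specialize(build_core_pattern(), catalog.get_model(name))


# ---------------------------------------------------------------------------
# Core pattern structure


def test_core_pattern_covers_five_primary_categories():
    pattern = build_core_pattern()
    categories = {n.category for n in pattern.nodes}
    assert categories == {"entity", "role", "process", "attribute", "identifier"}
    assert len(pattern.nodes) == 6  # entity contributes person + output


def test_person_connects_to_process_only_via_role():
    pattern = build_core_pattern()
    pairs = {(e.subject, e.object) for e in pattern.edges}
    assert ("role", "person") in pairs and ("role", "process") in pairs
    assert ("person", "process") not in pairs and ("process", "person") not in pairs


def test_identifier_attaches_only_to_role():
    pattern = build_core_pattern()
    attached = {
        other
        for e in pattern.edges
        for other, me in ((e.object, e.subject), (e.subject, e.object))
        if me == "identifier"
    }
    assert attached == {"role"}
    # ... and carries the pseudonym as its literal value
    assert any(s.node == "identifier" and s.column == "pid" for s in pattern.literal_slots)


def test_process_has_outgoing_output_edge():
    pattern = build_core_pattern()
    rel = pattern.vocab["relations"]
    assert any(
        e.subject == "process" and e.predicate == rel["has-output"] and e.object == "output"
        for e in pattern.edges
    )


def test_attribute_linked_to_person_and_output():
    pattern = build_core_pattern()
    subjects_into_attribute = {
        e.subject for e in pattern.edges if e.object == "attribute"
    }
    assert subjects_into_attribute == {"person", "output"}


def test_every_node_has_base_type():
    for node in build_core_pattern().nodes:
        assert node.base_type_iri.startswith("http")


# ---------------------------------------------------------------------------
# Specialization


def test_specialize_patient_status_binds_death_date(catalog):
    pattern = _specialized(catalog, "patient_status")
    slots = [s for s in pattern.literal_slots if s.column == "death_date"]
    assert len(slots) == 1 and slots[0].datatype == XSD_DATE
    status = pattern.node("output:status")
    assert status.type_column == "status_uri"


def test_specialize_phenotyping_constrains_output_to_hpo(catalog):
    pattern = _specialized(catalog, "phenotyping")
    out = pattern.node("output:phenotype")
    assert out.type_column == "phenotype_uri"
    spec = catalog.get_model("phenotyping").column("phenotype_uri")
    assert spec.constraint.parent_iri.endswith("HP_0000118")


def test_specialize_diagnosis_links_container(catalog):
    pattern = _specialized(catalog, "diagnosis")
    rel = pattern.vocab["relations"]
    container_edges = [
        e for e in pattern.edges if e.object == "container" and e.predicate == rel["part-of"]
    ]
    assert container_edges, "diagnosis output must join the progression container"
    assert "{col:progression_id}" in pattern.node("container").iri_rule


def test_specialize_unknown_column_is_pattern_error(catalog):
    import dataclasses

    template = catalog.get_model("disability")
    broken = dataclasses.replace(template, process_type_column="no_such_col")
    with pytest.raises(Exception, match="no_such_col"):
        specialize(build_core_pattern(), broken)


# ---------------------------------------------------------------------------
# Instantiation


def _status_row(pid="P1", row_id="R1", status="http://purl.obolibrary.org/obo/NCIT_C28554", death="2019-01-02"):
    return RowRecord(
        row_id=row_id,
        pseudonym=pid,
        cells={"pid": pid, "row_id": row_id, "status_uri": status, "death_date": death},
    )


def test_instantiate_is_deterministic(catalog):
    pattern = _specialized(catalog, "patient_status")
    assert instantiate(pattern, _status_row()) == instantiate(pattern, _status_row())


def test_instantiate_dead_row_carries_date_literal_and_status_iri(catalog):
    ts = instantiate(_specialized(catalog, "patient_status"), _status_row())
    literals = {o for _, _, o in ts.triples if isinstance(o, Literal)}
    assert Literal("2019-01-02", XSD_DATE) in literals
    status_types = {
        o for s, p, o in ts.triples
        if p == RDF_TYPE and o == "http://purl.obolibrary.org/obo/NCIT_C28554"
    }
    assert status_types


def _pattern_walk_oracle(pattern, row, base=DEFAULT_BASE_IRI):
    """Independent triple enumeration by brute-force pattern walking."""
    present = {}
    for node in pattern.nodes:
        cells_ok = all(row.cells.get(c) for c in node.referenced_columns)
        present[node.node_id] = cells_ok
    expected = set()
    for node in pattern.nodes:
        if not present[node.node_id]:
            continue
        types = {node.base_type_iri}
        if node.specific_type:
            types.add(node.specific_type)
        if node.type_column and row.cells.get(node.type_column):
            types.add(row.cells[node.type_column])
        for t in types:
            expected.add((node.node_id, "a", t))
    for edge in pattern.edges:
        if present[edge.subject] and present[edge.object]:
            expected.add((edge.subject, edge.predicate, edge.object))
    for slot in pattern.literal_slots:
        value = row.pseudonym if slot.column == "pid" else row.cells.get(slot.column)
        if present[slot.node] and value:
            expected.add((slot.node, slot.property, ("lit", value, slot.datatype)))
    return expected


@pytest.mark.parametrize(
    "model", ["patient_status", "disease_history", "undiagnosed", "patient_consent"]
)
def test_instantiate_triple_count_matches_pattern_walk(catalog, cohort, model):
    pattern = _specialized(catalog, model)
    for row in cohort[model].rows[:5]:
        ts = instantiate(pattern, row)
        assert len(ts) == len(_pattern_walk_oracle(pattern, row))


def test_instantiate_missing_column_names_slot(catalog):
    pattern = _specialized(catalog, "patient_status")
    row = RowRecord(row_id="R1", pseudonym="P1", cells={"pid": "P1", "row_id": "R1"})
    with pytest.raises(InstantiationError, match="status_uri"):
        instantiate(pattern, row)


def test_node_iris_percent_encode_identifiers(catalog):
    pattern = _specialized(catalog, "phenotyping")
    row = RowRecord(
        row_id="R 1",
        pseudonym="P/1",
        cells={"pid": "P/1", "row_id": "R 1", "phenotype_uri": "http://purl.obolibrary.org/obo/HP_0001250"},
    )
    ts = instantiate(pattern, row)
    subjects = {s for s, _, _ in ts.triples}
    assert any(quote("P/1", safe="") in s for s in subjects)
    assert all(" " not in s for s in subjects)


# ---------------------------------------------------------------------------
# Whole-table transformation


def test_transform_empty_table(catalog, cohort):
    import dataclasses

    table = dataclasses.replace(cohort["patient_status"], rows=())
    assert len(transform_table(catalog.get_model("patient_status"), table)) == 0


@pytest.mark.parametrize("model", ["patient_status", "diagnosis", "disability"])
def test_transform_table_count_equals_summed_row_oracle(catalog, cohort, model):
    # one row per patient -> no cross-row sharing, so counts are additive
    template = catalog.get_model(model)
    pattern = _specialized(catalog, model)
    table = cohort[model]
    total = sum(len(_pattern_walk_oracle(pattern, row)) for row in table.rows)
    ts = transform_table(template, table)
    assert len(ts) == total
    process_type = pattern.node("process").base_type_iri
    assert len(ts.subjects_with_type(process_type)) >= len(table)


def test_shared_pid_yields_single_person_node(catalog):
    import dataclasses

    template = catalog.get_model("phenotyping")
    rows = tuple(
        RowRecord(
            row_id=f"R{i}",
            pseudonym="P1",
            cells={"pid": "P1", "row_id": f"R{i}",
                   "phenotype_uri": "http://purl.obolibrary.org/obo/HP_0001250"},
        )
        for i in range(2)
    )
    from cdefair.csv_template import CsvTable

    table = CsvTable(model_name="phenotyping", header=("pid", "row_id", "phenotype_uri"), rows=rows)
    ts = transform_table(template, table)
    person_type = build_core_pattern().node("person").base_type_iri
    assert len(ts.subjects_with_type(person_type)) == 1


def test_container_coherence_across_models(catalog, cohort):
    """Diagnosis and disease-history subgraphs meet in one container per
    (patient, episode)."""
    merged = transform_table(catalog.get_model("diagnosis"), cohort["diagnosis"]) | transform_table(
        catalog.get_model("disease_history"), cohort["disease_history"]
    )
    part_of = build_core_pattern().vocab["relations"]["part-of"]
    containers_from_diag = {
        o for s, p, o in merged.triples if p == part_of and "/diagnosis/" in s
    }
    containers_from_hist = {
        o for s, p, o in merged.triples if p == part_of and "/disease_history/" in s
    }
    assert containers_from_diag and containers_from_diag == containers_from_hist
    for container in containers_from_diag:
        assert re.fullmatch(rf"{re.escape(DEFAULT_BASE_IRI)}progression/[^/]+/[^/]+", container)


# ---------------------------------------------------------------------------
# Universal typing / role mediation over a fuzzed cohort


def test_emitted_nodes_are_universally_typed(catalog, cohort):
    for name, table in cohort.items():
        ts = transform_table(catalog.get_model(name), table)
        typed = {s for s, p, o in ts.triples if p == RDF_TYPE}
        for s, p, o in ts.triples:
            assert s in typed, f"untyped subject {s} in {name}"
            if isinstance(o, str) and p != RDF_TYPE:
                assert o in typed, f"untyped object {o} in {name}"


def test_no_direct_person_identifier_link(catalog, cohort):
    person_type = build_core_pattern().node("person").base_type_iri
    id_type = build_core_pattern().node("identifier").base_type_iri
    for name, table in cohort.items():
        ts = transform_table(catalog.get_model(name), table)
        persons = ts.subjects_with_type(person_type)
        identifiers = ts.subjects_with_type(id_type)
        for s, p, o in ts.triples:
            assert not (s in persons and o in identifiers)
            assert not (s in identifiers and o in persons)


# ---------------------------------------------------------------------------
# Extensions


def _process_edges(pattern):
    return [e for e in pattern.edges if e.subject == "process"]


def test_lab_measurement_adds_three_process_connections(catalog):
    core = _specialized(catalog, "disability")
    extended = extend_lab_measurement(
        core,
        "http://purl.obolibrary.org/obo/NCIT_C12801",  # body tissue
        "http://purl.obolibrary.org/obo/NCIT_C48807",  # measured compound
    )
    assert len(_process_edges(extended)) == len(_process_edges(core)) + 3
    # structurally identical elsewhere
    assert [e for e in extended.edges if e.subject != "process"] == [
        e for e in core.edges if e.subject != "process"
    ]


def test_prom_and_body_measurement_add_one_edge_each(catalog):
    core = _specialized(catalog, "disability")
    for extend in (extend_prom, extend_body_measurement):
        extended = extend(core)
        assert len(_process_edges(extended)) == len(_process_edges(core)) + 1
        id_edges = lambda p: [e for e in p.edges if "identifier" in (e.subject, e.object)]
        assert id_edges(extended) == id_edges(core)


def test_lab_measurement_instantiation_anchors_input_and_target(catalog):
    extended = extend_lab_measurement(
        _specialized(catalog, "disability"),
        "http://purl.obolibrary.org/obo/NCIT_C12801",
        "http://purl.obolibrary.org/obo/NCIT_C48807",
    )
    blood = "http://purl.obolibrary.org/obo/NCIT_C12434"
    haemoglobin = "http://purl.obolibrary.org/obo/NCIT_C16681"
    row = RowRecord(
        row_id="R1",
        pseudonym="P1",
        cells={
            "pid": "P1",
            "row_id": "R1",
            "tool_uri": "http://purl.obolibrary.org/obo/NCIT_C107391",
            "score": "12.5",
            "input_uri": blood,
            "target_uri": haemoglobin,
            "protocol_uri": "https://protocols.example.org/cbc",
        },
    )
    ts = instantiate(extended, row)
    process = next(iter(ts.subjects_with_type(extended.node("process").base_type_iri)))
    anchored = {o for s, p, o in ts.triples if s == process}
    assert blood in anchored and haemoglobin in anchored
    # inputs/targets are themselves typed with their constraining parents
    assert (blood, RDF_TYPE, "http://purl.obolibrary.org/obo/NCIT_C12801") in ts.triples


# ---------------------------------------------------------------------------
# Serialization


def test_serialize_round_trip_isomorphic(catalog, cohort):
    ts = transform_table(catalog.get_model("patient_status"), cohort["patient_status"])
    for fmt, parser_fmt in (("turtle", "turtle"), ("ntriples", "nt")):
        text = serialize(ts, fmt)
        parsed = Graph().parse(data=text, format=parser_fmt)
        assert isomorphic(parsed, to_rdflib(ts))
        assert from_rdflib(parsed).triples == ts.triples


def test_serialize_empty_tripleset():
    text = serialize(TripleSet(frozenset()), "ntriples")
    assert not [l for l in text.splitlines() if l.strip()]


def test_deterministic_ntriples_byte_identical(catalog, cohort):
    ts = transform_table(catalog.get_model("diagnosis"), cohort["diagnosis"])
    a = serialize(ts, "ntriples", deterministic=True)
    b = serialize(ts, "ntriples", deterministic=True)
    assert a == b
    assert a.splitlines() == sorted(a.splitlines())


def test_serialize_unknown_format_rejected(catalog):
    with pytest.raises(ValueError):
        serialize(TripleSet(frozenset()), "rdfxml")
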