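# cdefair

Semantic common-data-element (CDE) models for rare-disease registries, as a
self-contained Python toolkit.

Rare-disease patient data is scattered over hundreds of small,
non-coordinating registries. The EU Platform on Rare Disease Registration
defines 16 Common Data Elements — pseudonym, sex, date of birth, diagnosis,
consent, disability score, and so on — that every registry should capture,
but a list of elements alone does not make data interoperable: that also
takes shared data models, formats and semantics. `cdefair` implements the
FAIRification route built for this setting: registries export their data as
simple per-model **CSV files** (the "lingua franca" any curator can
produce), and the toolkit validates those files and transforms them into
richly typed RDF following a reusable **SIO-patterned semantic model**,
with generated **ShEx** shapes to check the result — entirely offline, with
no services, databases or downloads.

## The core model

Every CDE observation is represented by one instantiation of a five-element
graph pattern built from the SemanticScience Integrated Ontology (SIO):

```
identifier --denotes--> role --is-role-of-------> person
                         |                          |
                         +--participates-in--+      +--has-attribute--+
                                             v                        v
                                          process --has-output--> output --refers-to--> attribute
```

* the **person** connects to the recording **process** only indirectly,
  through the **role** they play in it (one individual may be both patient
  and physician);
* the pseudonym **identifier** attaches to the role, never to the person —
  identifiers belong to roles (a student id identifies you-as-student);
* the process **output** (an information artifact: a status record, a
  phenotype assertion, a test score) *refers to* an **attribute** of the
  person — the attribute and its measurement are distinct things;
* every node carries an ontological type; model templates add specific
  types (NCIT, HPO, ORDO classes) and literal slots on top of the generic
  base types.

Eleven model templates cover the 16 elements (patient status, personal
information, diagnosis, disease history, genetic diagnosis, care pathway,
consent, phenotyping, disability, undiagnosed, and a *disease progression*
container that groups the diagnosis-related subgraphs of one clinical
episode). Each template fixes a CSV contract — column names, strict
ISO 8601 dates, full ontology IRIs, controlled value sets, offline
descendant-of constraints — and two interchangeable transformation routes:

1. a **direct builder** (`transform_table`), and
2. an auto-generated **YARRRML/RML declarative mapping**
   (`generate_mapping` + `execute_mapping`),

which are guaranteed (and tested) to produce graph-isomorphic output. A
generated ShEx schema per model validates the emitted graphs, and a
replace-load pipeline orchestrates the whole thing over a folder of CSVs.

## Worked example

One deceased patient's status row, transformed by `examples/03_transform_to_rdf.py`:

```python
from cdefair import build_core_pattern, instantiate, load_catalog, serialize, specialize
from cdefair.csv_template import RowRecord

catalog = load_catalog()
pattern = specialize(build_core_pattern(), catalog.get_model("patient_status"))
row = RowRecord(row_id="R1", pseudonym="P001", cells={
    "pid": "P001", "row_id": "R1",
    "status_uri": catalog.binding("3.1", "Dead"), "death_date": "2019-01-02"})
print(serialize(instantiate(pattern, row), "turtle"))
```

prints 16 triples:

```turtle
<https://example.org/registry/person/P001/id> a sio:SIO_000115 ;
    sio:SIO_000020 <https://example.org/registry/person/P001/role> ;
    sio:SIO_000300 "P001"^^xsd:string .

<https://example.org/registry/patient_status/R1/output-status> a obo:NCIT_C25717,
        obo:NCIT_C28554,
        sio:SIO_000015 ;
    sio:SIO_000300 "2019-01-02"^^xsd:date ;
    sio:SIO_000628 <https://example.org/registry/person/P001/attr/patient_status-status> .

<https://example.org/registry/patient_status/R1/process> a sio:SIO_000006 ;
    sio:SIO_000229 <https://example.org/registry/patient_status/R1/output-status> .

<https://example.org/registry/person/P001> a sio:SIO_000498 ;
    sio:SIO_000008 <https://example.org/registry/person/P001/attr/patient_status-status> .

<https://example.org/registry/person/P001/role> a sio:SIO_000016 ;
    sio:SIO_000062 <https://example.org/registry/patient_status/R1/process> ;
    sio:SIO_000227 <https://example.org/registry/person/P001> .

<https://example.org/registry/person/P001/attr/patient_status-status> a sio:SIO_000614 .
```

The pseudonym literal hangs off the identifier, which denotes the role; the
output is typed both with the vital-status record class and with the
concrete "Dead" value (NCIT C28554) and carries the death date; the person
is linked to the process only through the role. Node IRIs are
deterministic functions of (base IRI, model, pseudonym/row id, slot), so
re-running a transformation reproduces the identical graph.

The other scripts under `examples/` each demonstrate one capability:
catalogue lookups, CSV validation, mapping generation/execution, ShEx
validation with a targeted mutation, and a full pipeline run.

## Command line

```bash
cdefair generate --out export/ --n 100 --seed 1   # synthetic cohort
cdefair validate export/                          # contract check, exit 1 on issues
cdefair shapes --out models/                      # ShEx + YARRRML per model
cdefair run export/ --out store/ --strict         # full replace-load pipeline
```

The store is a folder of sorted N-Triples files (one per model), rebuilt
atomically on every run: its content is a pure function of the input
folder, never of prior runs.

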