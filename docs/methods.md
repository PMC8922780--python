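# Methods

This note documents the models, contracts and numerical/design choices
behind `cdefair`, and what the synthetic cohorts used by the test suite do
and do not show about real registry data.

## The catalogue

The catalogue (`cdefair/data/catalog/`) holds the 16 EU RD Platform common
data elements and 11 semantic model templates, one YAML document per model
plus one for the elements — mirroring the one-page-per-model granularity
of the upstream template documentation. Element ids follow the platform's
`digit.digit` numbering. Two mapping choices deserve note:

* **Consent covers 7.1–7.4.** The consent model is reused for the several
  consent-like axes (consent for contact, consent for data reuse, sample
  availability, biobank reference), since no dedicated templates exist for
  7.3/7.4; the biobank element ("URL/No") is realized as an optional URL
  column whose absence means "No".
* **Undiagnosed (6.3) is its own template**, even though the element list
  folds it under diagnosis: it captures phenotypic anomalies (HPO) and/or
  a sequence variant (HGVS) for a patient without a definitive diagnosis.
  The two findings are modelled as two optional process outputs with the
  table-level rule that at least one must be present.

**Term bindings are configuration, not catalogue facts.** The element list
fixes controlled *labels* (Female, Dead, Antenatal, Yes…); the ontology
IRI behind each label lives in `bindings.yaml` and can be overridden per
run. The shipped defaults use NCIT for sex/status/yes-no values and HPO
onset classes for age-at-onset categories. They are defensible defaults,
not normative choices — a deployment reconciling against a specific
terminology release should override them.

Similarly, the relation and base-type vocabulary (`vocabulary.yaml`) maps
slot names (`role-of`, `participates-in`, `has-output`, `has-attribute`,
`has-value`, `denotes`, `refers-to`, `part-of`, `has-input`, `has-target`,
`has-protocol`) to SIO-style IRIs. Builder, mapping generator and ShEx
generator all reference slots, never raw IRIs, so swapping the vocabulary
is a data change.

## CSV contract

The exchange dialect is the lowest common denominator: comma separator,
double-quote escaping, UTF-8, one header row (RFC 4180 style). Canonical
column names are lower_snake_case per model; every model carries `pid`
(the pseudonym) and `row_id`. Diagnosis-linked models additionally carry
`progression_id`, the episode key that lets the disease-progression
container group rows across files; this cross-file mechanism is a design
choice of this artifact (the container's *role* is given, its CSV
realization is not).

Validation is total and side-effect free: all issues are collected (never
first-failure), each as a `(row_id, column, code)` record with a
code-determined message. Codes: `missing_required`, `bad_date`, `bad_iri`,
`not_in_value_set` (also used for regex-pattern misses, which have no
dedicated code), `not_descendant`, `duplicate_row_id` (reported once per
participating row), `bad_number`.

* **Dates** must be strict ISO 8601 calendar dates (`YYYY-MM-DD`): no time
  component, no compact/week/slash dialects. The registry-facing
  `dd/mm/yyyy` convention is deliberately rejected; conversion is the
  custodian's export step.
* **Ontology membership** is checked offline against bundled
  descendant-or-self closures (`closures/term_closures.yaml`): small
  *samples* of the real HPO phenotypic-abnormality branch, ORDO clinical
  entities, NCIT assessment tools and NCIT personal attributes — tens of
  terms, not full ontologies. A closure missing the constraint's parent is
  a configuration error, not a data issue.
* **Row ids** can be minted deterministically from (timestamp, sequence)
  via `mint_row_id`, a local stand-in for a timestamp-based GUID service;
  the format (`R<stamp>-<seq>`) is artifact-defined and opaque.

Two optional pre-processing helpers are off by default: label→IRI
translation (repairing exports that still carry bare labels) and
birth-date degradation to year (`privacy.birth_date_as_year` in the run
config), which swaps the emitted literal to `xsd:gYear`. Degradation is a
cell-level rewrite applied before transformation so that the builder and
the mapping route stay equivalent; emitting the full date is the default
because the choice is explicitly unsettled at the modelling level.

## Graph building

`build_core_pattern` returns the model-independent pattern: six nodes
(person, role, identifier, process, output, attribute) covering five
primary element categories, wired with the minimal relation set and all
nodes ontologically typed (the process always as the generic process
class). `specialize` binds it to a template: one output node per declared
output slot (with a fixed specific type, an optional per-row type taken
from a column, and literal slots), one attribute node per
attribute-bearing output, and — for linked models — a `part-of` edge from
each output into the container node keyed by `(pid, progression_id)`.

**IRI minting.** Node IRIs are readable templates over
`(base IRI, model, pid or row_id, slot)`, percent-encoding substituted
values: `person/{pid}`, `person/{pid}/role`, `{model}/{row_id}/process`,
`progression/{pid}/{progression_id}`, … They are pure functions of those
keys, which gives bit-identical re-runs (the property the replace-load
store relies on) while keeping graphs debuggable; an opaque hash would be
equally deterministic but was not needed. Blank nodes are never emitted —
every node has a minted IRI, enabling graph diffing and ShEx focus
selection.

**Presence semantics.** A node whose IRI rule references an empty cell is
absent for that row, together with its edges and literals; an empty
optional cell produces no triples for its slot. Optional outputs (the
gene of a genetic diagnosis, the biobank reference, either finding of an
undiagnosed case) embed their presence column in the IRI rule, so the
same suppression rule drives both the builder and the RML executor —
conditional logic is never needed.

**Typed values.** Controlled column values (status, sex, diagnosis,
phenotype…) must already be IRIs in the CSV and become additional
`rdf:type` assertions on the output node (the patient-status output of a
deceased patient is typed both with the vital-status record class and
with the "Dead" class). Literals are datatyped (`xsd:date` for all CDE
dates — no datetime promotion, `xsd:decimal` for scores, `xsd:anyURI` for
the biobank URL).

**Extensions.** Three pattern variants demonstrate that the core is not
overfitted to the CDEs: lab measurements add exactly three process
connections (a tissue-constrained input, a compound-constrained target,
and a protocol link), patient-reported outcomes add one (the question as
process input), body measurements add one (the protocol link). Extension
node IRIs are the referenced column values themselves, typed with their
constraining parent class; everything outside the process node is
structurally identical to the core.

## Declarative mappings

`generate_mapping` converts a specialized pattern into a YARRRML-style
document: one triple map per node, subject templates with `$(column)`
variables, `a`-assertions for types, `{mapping: other}` references for
edges, `{value, datatype}` pairs for literals. Only the RML subset these
patterns need is executed: row iteration, template substitution
(percent-encoded, except that an object consisting of exactly one
variable is taken verbatim as an IRI), datatyped literals, and cross-map
references resolved as the referenced map's subject over the same row —
which subsumes join-on-shared-column semantics because all node IRIs are
deterministic row functions. No functions or conditions exist in the
dialect, and unknown YAML keys are rejected loudly.

The builder and the executor are two genuinely separate code paths over
the same pattern; their graph-isomorphism on every model × seeded cohort
is the module's central tested property (exact triple-set equality holds
as well, since neither route emits blank nodes).

## ShEx schemas and validation

`generate_shape` mirrors the specialized pattern: one shape per node,
anchored to the node's ontological type (the fixed specific type for
outputs, the base type otherwise). Required edges get cardinality 1..1;
edges that legitimately accumulate across rows on shared nodes — a role
participating in many recording processes, a person bearing attributes
from many rows — get 1..\*. Optional literal slots get 0..1, controlled
`rdf:type` values a value-set constraint. The death-date conditionality
("required iff status is Dead") is encoded as two alternative shapes
discriminated by the Dead type, one requiring the date (1..1), the other
forbidding it ({0,0}), keeping the schema subset condition-free.

The validator implements exactly this subset: focus nodes selected by
`rdf:type`, conjunctive triple constraints with filter-then-count
semantics (a constraint counts only objects matching its value
constraint, so several constraints on `rdf:type` coexist without EachOf
ambiguity), datatype checks including lexical validity for
date/decimal/integer/gYear, and one-level shape references (the object
must carry the referred shape's anchor type). Schemas are tree-shaped by
construction, so deeper recursion is unnecessary. Serialization is ShExC;
a strict parser for the emitted subset doubles as a well-formedness
oracle in the tests, since no independent ShEx engine is available in the
toolkit's dependency set.

The mutation-sensitivity property is stated carefully: deleting any
*individually required* edge — one whose matching count at its focus node
equals the constraint minimum — produces exactly one new nonconformance.
An edge with redundancy (one of several attributes on a shared person
node) is not individually required, and its deletion is not expected to
be caught; the acceptance check therefore runs on one-row-per-patient
cohorts where required counts are exactly 1.

## Synthetic cohorts

The generator emulates a multi-file registry export under fixed study
conditions: shared pseudonyms across all 11 model files, one row per
patient per included model (Bernoulli inclusion, default probability 1),
dates sampled uniformly in the window (default 1950-01-01..2020-12-31)
and then ordered so that birth < onset ≤ diagnosis ≤ first contact, a
death date present iff the status is Dead (sampled 80/10/5/5 over
Alive/Dead/Lost/Opted-out) and after birth, controlled cells drawn from
the catalogue bindings and bundled closures, and a shared episode id so
diagnosis-linked files stay referentially intact (patients with a
diagnosis row always also get disease-history and container rows). Row
ids come from the deterministic minting service over a fixed clock epoch.
Output is byte-deterministic under a fixed seed.

The corruptor injects one violation per selected row (per-row Bernoulli
at the requested rate), choosing among the requested issue codes with
per-kind candidate columns and per-kind corrupt values guaranteed to
trigger exactly the ledgered code; duplicate row ids copy the already
final id of the preceding row so the pair survives later injections. The
test suite asserts 100% recall of the ledger and zero false positives on
uncorrupted output.

What this does **not** show about real data: realistic disease
prevalence, survival, multi-episode histories, free-text noise, encoding
errors beyond the modelled codes, or terminology drift between ontology
releases. Passing tests demonstrate the contracts and transformations,
not epidemiological plausibility.

## Pipeline

Discovery matches files to models by normalized basename prefix (longest
model name wins, so `genetic_diagnosis_*.csv` is never claimed by
`diagnosis`); unmatched CSVs are reported, never silently skipped. A run
validates everything first; in strict mode any issue aborts before the
store is touched, in lenient mode rows carrying issues are skipped (and
counted) and the clean remainder is transformed. Transformation uses the
direct builder by default or the mapping executor (`--mode mapping`);
both feed the same ShEx check. The store — one sorted N-Triples file per
model, standing in for a triple-store repository — is built in a staging
sibling directory and swapped in by rename, so prior content is fully
replaced and a crash never leaves a partial store. With the determinism
flag (default on) store bytes are a pure function of the input folder.

The orchestration deliberately replaces service deployment (container
stacks, triple-store APIs, web triggers, remote template refresh) with
local files and a CLI; mapping documents are generated from the bundled
catalogue, with `cdefair shapes` available to export them for external
engines.

## Problem sizes and tolerances

The test suite uses 10–200 patient cohorts (one row per patient per
model) for property and equivalence checks, chosen to exercise every
model and branch while keeping the default run fast; the scale check
transforms a 10,000-row patient-status table (~151k triples) end-to-end.
Date fuzzing runs 300 derandomized examples against an independent
strict-parse oracle. All equivalence checks are exact (triple-set
equality / graph isomorphism); no numerical tolerances are involved
anywhere in the package.

## Known limitations

* The SIO predicate/base-type IRIs and several NCIT output-record classes
  are configured defaults chosen for plausibility, not reconciled against
  any published exemplar; the vocabulary and bindings files are the
  single place to fix them.
* The ShEx subset cannot express "at least one of" across two different
  predicates, so the undiagnosed model's both-findings-absent case is
  caught by CSV validation only.
* Term closures are bundled samples; real deployments need closure files
  generated from full ontology releases.
* The RML executor handles exactly the generated dialect (CSV source, row
  iterator, templates, literals, map references) — it is not a general
  RML engine.
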