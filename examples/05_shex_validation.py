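"""Generate a ShEx schema, validate a cohort graph, and catch a mutation.

Prints the compact-syntax schema for the patient-status model, validates
a clean synthetic cohort (everything conforms), then deletes one required
death-date triple and shows the resulting nonconformance.
"""

from cdefair import (
    CohortConfig,
    generate_cohort,
    generate_shape,
    load_catalog,
    transform_table,
    validate_graph,
)
from cdefair.shex import serialize_shexc
from cdefair.sio_graph import Literal, TripleSet

catalog = load_catalog()
template = catalog.get_model("patient_status")
schema = generate_shape(template)
print(serialize_shexc(schema))

table = generate_cohort(CohortConfig(n_patients=30, seed=2), catalog)["patient_status"]
graph = transform_table(template, table)
report = validate_graph(schema, graph)
print(f"clean cohort: {report.summary}")

date_triple = next(
    t for t in graph.triples
    if isinstance(t[2], Literal) and t[2].datatype.endswith("date")
)
mutated = TripleSet(graph.triples - {date_triple}, graph.namespaces)
report = validate_graph(schema, mutated)
print(f"after deleting one death date: {report.summary}")
for result in report.nonconforming():
    print(f"  {result.node}\n    {result.reason}")
# Exactly one focus node fails: the output of the deceased patient whose
# required death-date literal was removed.
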