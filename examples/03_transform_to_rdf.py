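"""Transform one patient-status row into the SIO-patterned RDF graph.

Prints the Turtle for a single deceased patient: the person connects to
the recording process via their patient role, the pseudonym hangs off the
role's identifier, and the process output carries the status class and
the death date.
"""

from cdefair import build_core_pattern, instantiate, load_catalog, serialize, specialize
from cdefair.csv_template import RowRecord

catalog = load_catalog()
pattern = specialize(build_core_pattern(), catalog.get_model("patient_status"))

row = RowRecord(
    row_id="R1",
    pseudonym="P001",
    cells={
        "pid": "P001",
        "row_id": "R1",
        "status_uri": catalog.binding("3.1", "Dead"),
        "death_date": "2019-01-02",
    },
)
triples = instantiate(pattern, row)
print(f"{len(triples)} triples for one row:\n")
print(serialize(triples, "turtle"))
# Note: no direct person->identifier link, and no direct person->process
# link -- both are mediated by the role, as the core pattern requires.
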