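"""Validate a registry CSV export against its model contract.

Builds a tiny patient-status file with two deliberate mistakes (a
registry-dialect date and a bare label instead of an IRI) and prints the
issue report a data custodian would receive.
"""

import tempfile
from pathlib import Path

from cdefair import load_catalog, load_term_closures, parse_csv, validate_table
from cdefair.csv_template import issues_to_text

CSV = """\
pid,row_id,status_uri,death_date
P001,R1,http://purl.obolibrary.org/obo/NCIT_C37987,
P002,R2,http://purl.obolibrary.org/obo/NCIT_C28554,02/01/2019
P003,R3,Dead,
"""

catalog = load_catalog()
template = catalog.get_model("patient_status")

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "patient_status.csv"
    path.write_text(CSV)
    table = parse_csv(path, template)
    issues = validate_table(table, template, load_term_closures())

print(f"{len(table)} rows, {len(issues)} issue(s):\n")
print(issues_to_text(issues))
# bad_date: the export must use strict ISO 8601 (YYYY-MM-DD), not dd/mm/yyyy;
# bad_iri: controlled values must be full ontology IRIs, not labels.
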