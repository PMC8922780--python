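model_name: patient_status
purpose: >
  Captures the current status of the patient, and their date of death if
  the patient is deceased.
covered_element_ids: ["1.1", "3.1", "3.2"]
links_to: []
columns:
  - {name: pid, datatype: string, required: true}
  - {name: row_id, datatype: string, required: true}
  - name: status_uri
    datatype: iri
    required: true
    constraint: {value_set_element: "3.1"}
  - {name: death_date, datatype: iso_date, required: false}
outputs:
  - name: status
    fixed_type: http://purl.obolibrary.org/obo/NCIT_C25717
    type_column: status_uri
    literals:
      - {column: death_date, datatype: xsd:date}
conditional:
  output: status
  element: "3.1"
  when_label: Dead
  require_literal: death_date
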