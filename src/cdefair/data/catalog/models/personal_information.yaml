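model_name: personal_information
purpose: >
  Captures (superficial) personal information such as birth date and sex.
  Birth date may optionally be degraded to a year for improved privacy via
  the run configuration.
covered_element_ids: ["1.1", "2.1", "2.2"]
links_to: []
columns:
  - {name: pid, datatype: string, required: true}
  - {name: row_id, datatype: string, required: true}
  - {name: birth_date, datatype: iso_date, required: true}
  - name: sex_uri
    datatype: iri
    required: true
    constraint: {value_set_element: "2.2"}
outputs:
  - name: birth
    fixed_type: http://purl.obolibrary.org/obo/NCIT_C68615
    literals:
      - {column: birth_date, datatype: xsd:date, required: true}
  - name: sex
    fixed_type: http://purl.obolibrary.org/obo/NCIT_C28421
    type_column: sex_uri
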