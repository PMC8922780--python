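model_name: disease_history
purpose: >
  Captures age at first symptoms (onset) and age at diagnosis, either as a
  category or as a date; is connected to disease progression.
covered_element_ids: ["1.1", "5.1", "5.2"]
links_to: [disease_progression]
columns:
  - {name: pid, datatype: string, required: true}
  - {name: row_id, datatype: string, required: true}
  - {name: progression_id, datatype: string, required: true}
  - name: onset_category_uri
    datatype: iri
    required: false
    constraint: {value_set_element: "5.1"}
  - {name: onset_date, datatype: iso_date, required: false}
  - name: diagnosis_category_uri
    datatype: iri
    required: false
    constraint: {value_set_element: "5.2"}
  - {name: diagnosis_date, datatype: iso_date, required: false}
at_least_one_of:
  - [onset_category_uri, onset_date]
  - [diagnosis_category_uri, diagnosis_date]
outputs:
  - name: onset
    fixed_type: http://purl.obolibrary.org/obo/NCIT_C124353
    type_column: onset_category_uri
    literals:
      - {column: onset_date, datatype: xsd:date}
  - name: diagnosis_age
    fixed_type: http://purl.obolibrary.org/obo/NCIT_C156420
    type_column: diagnosis_category_uri
    literals:
      - {column: diagnosis_date, datatype: xsd:date}
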