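model_name: disability
purpose: >
  Captures the score for a disability test. The specific test administered
  is indicated as a child of the clinical-or-research-assessment-tool class,
  making the model broadly useful for many disorders.
covered_element_ids: ["1.1", "8.1"]
links_to: []
columns:
  - {name: pid, datatype: string, required: true}
  - {name: row_id, datatype: string, required: true}
  - name: tool_uri
    datatype: iri
    required: true
    constraint: {descendant_of: "http://purl.obolibrary.org/obo/NCIT_C20993"}
  - {name: score, datatype: decimal, required: true}
process_type_column: tool_uri
outputs:
  - name: score
    fixed_type: http://purl.obolibrary.org/obo/NCIT_C25338
    literals:
      - {column: score, datatype: xsd:decimal, required: true}
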