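model_name: diagnosis
purpose: >
  Captures the final disease diagnosis using ORPHA codes; is connected to
  disease progression.
covered_element_ids: ["1.1", "6.1"]
links_to: [disease_progression]
columns:
  - {name: pid, datatype: string, required: true}
  - {name: row_id, datatype: string, required: true}
  - {name: progression_id, datatype: string, required: true}
  - name: diagnosis_uri
    datatype: iri
    required: true
    constraint: {descendant_of: "http://www.orpha.net/ORDO/Orphanet_C001"}
outputs:
  - name: diagnosis
    fixed_type: http://purl.obolibrary.org/obo/NCIT_C15220
    type_column: diagnosis_uri
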