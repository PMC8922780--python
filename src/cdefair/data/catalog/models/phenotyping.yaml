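model_name: phenotyping
purpose: >
  Captures the phenotypes of the patient, using Human Phenotype Ontology
  terms.
covered_element_ids: ["1.1"]
links_to: []
columns:
  - {name: pid, datatype: string, required: true}
  - {name: row_id, datatype: string, required: true}
  - name: phenotype_uri
    datatype: iri
    required: true
    constraint: {descendant_of: "http://purl.obolibrary.org/obo/HP_0000118"}
outputs:
  - name: phenotype
    fixed_type: http://purl.obolibrary.org/obo/NCIT_C16977
    type_column: phenotype_uri
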