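model_name: undiagnosed
purpose: >
  Captures the case where a patient has phenotypic anomalies, and/or an
  identified sequence variant, but has not been definitively diagnosed.
  At least one of the two findings must be present.
covered_element_ids: ["1.1", "6.3"]
links_to: []
columns:
  - {name: pid, datatype: string, required: true}
  - {name: row_id, datatype: string, required: true}
  - name: phenotype_uri
    datatype: iri
    required: false
    constraint: {descendant_of: "http://purl.obolibrary.org/obo/HP_0000118"}
  - name: variant_hgvs
    datatype: string
    required: false
    constraint: {regex: "N[MC]_\\d+(\\.\\d+)?:[cg]\\..+"}
at_least_one_of:
  - [phenotype_uri, variant_hgvs]
outputs:
  - name: phenotype
    fixed_type: http://purl.obolibrary.org/obo/NCIT_C16977
    type_column: phenotype_uri
    presence_column: phenotype_uri
  - name: variant
    fixed_type: http://purl.obolibrary.org/obo/SO_0001060
    presence_column: variant_hgvs
    attribute: false
    literals:
      - {column: variant_hgvs, datatype: xsd:string, required: true}
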