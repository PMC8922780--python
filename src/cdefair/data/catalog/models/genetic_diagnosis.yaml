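model_name: genetic_diagnosis
purpose: >
  Captures the sequence variant(s) found in this patient using HGVS notation
  and the affected gene; is connected to disease progression.
covered_element_ids: ["1.1", "6.2"]
links_to: [disease_progression]
columns:
  - {name: pid, datatype: string, required: true}
  - {name: row_id, datatype: string, required: true}
  - {name: progression_id, datatype: string, required: true}
  - name: variant_hgvs
    datatype: string
    required: true
    constraint: {regex: "N[MC]_\\d+(\\.\\d+)?:[cg]\\..+"}
  - name: gene_uri
    datatype: iri
    required: false
    constraint: {regex: "https://identifiers\\.org/hgnc/\\d+"}
outputs:
  - name: variant
    fixed_type: http://purl.obolibrary.org/obo/SO_0001060
    literals:
      - {column: variant_hgvs, datatype: xsd:string, required: true}
  - name: gene
    fixed_type: http://purl.obolibrary.org/obo/NCIT_C16612
    type_column: gene_uri
    presence_column: gene_uri
    attribute: false
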