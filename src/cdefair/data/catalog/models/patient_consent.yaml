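model_name: patient_consent
purpose: >
  Captures the consent of the patient over several axes (consent for
  contact, consent for data reuse), plus availability of a biological
  sample and the biobank holding it.
covered_element_ids: ["1.1", "7.1", "7.2", "7.3", "7.4"]
links_to: []
columns:
  - {name: pid, datatype: string, required: true}
  - {name: row_id, datatype: string, required: true}
  - name: consent_contact_uri
    datatype: iri
    required: true
    constraint: {value_set_element: "7.1"}
  - name: consent_reuse_uri
    datatype: iri
    required: true
    constraint: {value_set_element: "7.2"}
  - name: sample_available_uri
    datatype: iri
    required: true
    constraint: {value_set_element: "7.3"}
  - name: biobank_url
    datatype: string
    required: false
    constraint: {regex: "https?://\\S+"}
outputs:
  - name: contact_consent
    fixed_type: http://purl.obolibrary.org/obo/NCIT_C176662
    type_column: consent_contact_uri
  - name: reuse_consent
    fixed_type: http://purl.obolibrary.org/obo/NCIT_C176663
    type_column: consent_reuse_uri
  - name: sample_available
    fixed_type: http://purl.obolibrary.org/obo/NCIT_C19157
    type_column: sample_available_uri
  - name: biobank
    fixed_type: http://purl.obolibrary.org/obo/NCIT_C115935
    presence_column: biobank_url
    attribute: false
    literals:
      - {column: biobank_url, datatype: xsd:anyURI, required: true}
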