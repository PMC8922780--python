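model_name: care_pathway
purpose: >
  Captures the date of first contact with the specialist healthcare system;
  is connected to disease progression.
covered_element_ids: ["1.1", "4.1"]
links_to: [disease_progression]
columns:
  - {name: pid, datatype: string, required: true}
  - {name: row_id, datatype: string, required: true}
  - {name: progression_id, datatype: string, required: true}
  - {name: first_contact_date, datatype: iso_date, required: true}
outputs:
  - name: first_contact
    fixed_type: http://purl.obolibrary.org/obo/NCIT_C159705
    literals:
      - {column: first_contact_date, datatype: xsd:date, required: true}
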