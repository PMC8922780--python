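# The 16 common data elements of the EU rare-disease registration platform.
# Controlled labels are bound to ontology IRIs in bindings.yaml.
elements:
  - element_id: "1.1"
    name: Pseudonym
    value_kind: free_string
  - element_id: "2.1"
    name: Date of birth
    value_kind: iso_date
  - element_id: "2.2"
    name: Sex
    value_kind: controlled_term
    allowed_labels: [Female, Male, Undetermined, "Foetus (Unknown)"]
  - element_id: "3.1"
    name: Patient Status
    value_kind: controlled_term
    allowed_labels: [Alive, Dead, "Lost in Follow-up", "Opted-out"]
  - element_id: "3.2"
    name: Date of Death
    value_kind: iso_date
  - element_id: "4.1"
    name: First contact with specialized centre
    value_kind: iso_date
  - element_id: "5.1"
    name: Age at onset
    value_kind: controlled_term
    allowed_labels: [Antenatal, "At Birth", Undetermined]
  - element_id: "5.2"
    name: Age at diagnosis
    value_kind: controlled_term
    allowed_labels: [Antenatal, "At Birth", Undetermined]
  - element_id: "6.1"
    name: Diagnosis of the rare disease
    value_kind: ontology_class_constrained
    parent_class_iri: http://www.orpha.net/ORDO/Orphanet_C001
  - element_id: "6.2"
    name: Genetic Diagnosis
    value_kind: free_string
  - element_id: "6.3"
    name: Undiagnosed case
    value_kind: ontology_class_constrained
    parent_class_iri: http://purl.obolibrary.org/obo/HP_0000118
  - element_id: "7.1"
    name: Agreement to be contacted for research purposes
    value_kind: boolean_yes_no
    allowed_labels: ["Yes", "No"]
  - element_id: "7.2"
    name: Consent to reuse data
    value_kind: boolean_yes_no
    allowed_labels: ["Yes", "No"]
  - element_id: "7.3"
    name: Biological Sample
    value_kind: boolean_yes_no
    allowed_labels: ["Yes", "No"]
  - element_id: "7.4"
    name: Biobank
    value_kind: url_or_no
  - element_id: "8.1"
    name: Disability Classification (ICF)
    value_kind: numeric_score
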