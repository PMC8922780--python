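model_name: disease_progression
purpose: >
  A container node grouping together all other CDE records that refer to the
  same diagnosis: age at diagnosis, care pathway, disease history and genetic
  findings are reachable by traversal into this container.
covered_element_ids: ["1.1"]
links_to: []
columns:
  - {name: pid, datatype: string, required: true}
  - {name: row_id, datatype: string, required: true}
  - {name: progression_id, datatype: string, required: true}
outputs:
  - name: container
    container: true
    fixed_type: http://semanticscience.org/resource/SIO_000616
    attribute: false
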