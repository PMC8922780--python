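# Relation and base-type vocabulary for the SIO-patterned graph builder.
# Builder logic refers to slot names only; the IRI behind each slot is
# configuration (overridable through a run-config "vocabulary" section).
# Defaults follow the SemanticScience Integrated Ontology numbering.
prefixes:
  sio: http://semanticscience.org/resource/
  obo: http://purl.obolibrary.org/obo/
  ordo: http://www.orpha.net/ORDO/
  xsd: http://www.w3.org/2001/XMLSchema#
  rdf: http://www.w3.org/1999/02/22-rdf-syntax-ns#
relations:
  role-of: http://semanticscience.org/resource/SIO_000227
  participates-in: http://semanticscience.org/resource/SIO_000062
  has-output: http://semanticscience.org/resource/SIO_000229
  has-input: http://semanticscience.org/resource/SIO_000230
  has-attribute: http://semanticscience.org/resource/SIO_000008
  has-value: http://semanticscience.org/resource/SIO_000300
  denotes: http://semanticscience.org/resource/SIO_000020
  refers-to: http://semanticscience.org/resource/SIO_000628
  part-of: http://semanticscience.org/resource/SIO_000068
  has-target: http://semanticscience.org/resource/SIO_000291
  has-protocol: http://semanticscience.org/resource/SIO_001278
base_types:
  person: http://semanticscience.org/resource/SIO_000498
  role: http://semanticscience.org/resource/SIO_000016
  process: http://semanticscience.org/resource/SIO_000006
  attribute: http://semanticscience.org/resource/SIO_000614
  information-entity: http://semanticscience.org/resource/SIO_000015
  identifier: http://semanticscience.org/resource/SIO_000115
  collection: http://semanticscience.org/resource/SIO_000616
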