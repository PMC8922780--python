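# Controlled-value bindings: per element, label -> ontology term IRI.
# The element catalogue fixes the labels; the IRI chosen for each label is
# configuration (overridable through a run-config "bindings" section), since
# registries may prefer different terminology releases.
"2.2":
  Female: http://purl.obolibrary.org/obo/NCIT_C16576
  Male: http://purl.obolibrary.org/obo/NCIT_C20197
  Undetermined: http://purl.obolibrary.org/obo/NCIT_C45908
  "Foetus (Unknown)": http://purl.obolibrary.org/obo/NCIT_C17998
"3.1":
  Alive: http://purl.obolibrary.org/obo/NCIT_C37987
  Dead: http://purl.obolibrary.org/obo/NCIT_C28554
  "Lost in Follow-up": http://purl.obolibrary.org/obo/NCIT_C70740
  "Opted-out": http://purl.obolibrary.org/obo/NCIT_C142610
"5.1":
  Antenatal: http://purl.obolibrary.org/obo/HP_0030674
  "At Birth": http://purl.obolibrary.org/obo/HP_0003577
  Undetermined: http://purl.obolibrary.org/obo/NCIT_C38046
"5.2":
  Antenatal: http://purl.obolibrary.org/obo/HP_0030674
  "At Birth": http://purl.obolibrary.org/obo/HP_0003577
  Undetermined: http://purl.obolibrary.org/obo/NCIT_C38046
"7.1":
  "Yes": http://purl.obolibrary.org/obo/NCIT_C49488
  "No": http://purl.obolibrary.org/obo/NCIT_C49487
"7.2":
  "Yes": http://purl.obolibrary.org/obo/NCIT_C49488
  "No": http://purl.obolibrary.org/obo/NCIT_C49487
"7.3":
  "Yes": http://purl.obolibrary.org/obo/NCIT_C49488
  "No": http://purl.obolibrary.org/obo/NCIT_C49487
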