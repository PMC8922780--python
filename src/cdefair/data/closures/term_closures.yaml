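# Sample ontology term closures for offline descendant-of validation.
# Each key is a parent class; the list is a small descendant-or-self sample
# of the real ontology branch (NOT the full ontology), sufficient for
# constraint checking on template-compliant exports. Every parent is a
# member of its own closure.
http://purl.obolibrary.org/obo/HP_0000118:   # phenotypic abnormality
  - http://purl.obolibrary.org/obo/HP_0000118
  - http://purl.obolibrary.org/obo/HP_0000252   # microcephaly
  - http://purl.obolibrary.org/obo/HP_0000365   # hearing impairment
  - http://purl.obolibrary.org/obo/HP_0000505   # visual impairment
  - http://purl.obolibrary.org/obo/HP_0001156   # brachydactyly
  - http://purl.obolibrary.org/obo/HP_0001250   # seizure
  - http://purl.obolibrary.org/obo/HP_0001263   # global developmental delay
  - http://purl.obolibrary.org/obo/HP_0001324   # muscle weakness
  - http://purl.obolibrary.org/obo/HP_0001508   # failure to thrive
  - http://purl.obolibrary.org/obo/HP_0001627   # abnormal heart morphology
  - http://purl.obolibrary.org/obo/HP_0001903   # anemia
  - http://purl.obolibrary.org/obo/HP_0002721   # immunodeficiency
  - http://purl.obolibrary.org/obo/HP_0004322   # short stature
http://www.orpha.net/ORDO/Orphanet_C001:     # clinical entity (ORDO root)
  - http://www.orpha.net/ORDO/Orphanet_C001
  - http://www.orpha.net/ORDO/Orphanet_324    # Fabry disease
  - http://www.orpha.net/ORDO/Orphanet_355    # Gaucher disease
  - http://www.orpha.net/ORDO/Orphanet_558    # Marfan syndrome
  - http://www.orpha.net/ORDO/Orphanet_586    # cystic fibrosis
  - http://www.orpha.net/ORDO/Orphanet_636    # neurofibromatosis type 1
  - http://www.orpha.net/ORDO/Orphanet_648    # Noonan syndrome
  - http://www.orpha.net/ORDO/Orphanet_739    # Prader-Willi syndrome
  - http://www.orpha.net/ORDO/Orphanet_881    # Turner syndrome
  - http://www.orpha.net/ORDO/Orphanet_98896  # Duchenne muscular dystrophy
http://purl.obolibrary.org/obo/NCIT_C20993:  # clinical or research assessment tool
  - http://purl.obolibrary.org/obo/NCIT_C20993
  - http://purl.obolibrary.org/obo/NCIT_C107391
  - http://purl.obolibrary.org/obo/NCIT_C121007
  - http://purl.obolibrary.org/obo/NCIT_C125004
  - http://purl.obolibrary.org/obo/NCIT_C181535
http://purl.obolibrary.org/obo/NCIT_C19332:  # personal attribute
  - http://purl.obolibrary.org/obo/NCIT_C19332
  - http://purl.obolibrary.org/obo/NCIT_C25208   # weight
  - http://purl.obolibrary.org/obo/NCIT_C25347   # height
  - http://purl.obolibrary.org/obo/NCIT_C16358   # body mass index
  - http://purl.obolibrary.org/obo/NCIT_C54706   # blood pressure
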