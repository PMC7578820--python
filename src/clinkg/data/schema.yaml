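version: 1
classes:
  - name: patient
    parent: null
    source: ""
    data_properties: [ID, sex, age, occupation, native place]
  - name: disease
    parent: null
    source: "SNOMED CT, ICD-10"
    data_properties: [English name, nonpreferred term, state]
  - name: noncancerous disease
    parent: disease
    source: "SNOMED CT, ICD-10"
    data_properties: []
  - name: cancer
    parent: disease
    source: "SNOMED CT, ICD-10"
    data_properties: []
  - name: disease type
    parent: null
    source: "WHO"
    data_properties: [English name, nonpreferred term, histological grade, pathological stage,
      naked eye type, tumor size]
  - name: test
    parent: null
    source: "SNOMED CT, ICD-10"
    data_properties: [English name, nonpreferred term]
  - name: laboratory test
    parent: test
    source: "SNOMED CT"
    data_properties: []
  - name: imaging examination
    parent: test
    source: "SNOMED CT"
    data_properties: []
  - name: endoscopic examination
    parent: test
    source: "SNOMED CT"
    data_properties: []
  - name: pathological examination
    parent: test
    source: "SNOMED CT"
    data_properties: []
  - name: body structure
    parent: null
    source: "SNOMED CT"
    data_properties: [English name, nonpreferred term]
  - name: clinical finding
    parent: null
    source: "SNOMED CT"
    data_properties: [English name, nonpreferred term, state]
  - name: symptom
    parent: clinical finding
    source: "SNOMED CT"
    data_properties: []
  - name: sign
    parent: clinical finding
    source: "SNOMED CT"
    data_properties: []
  - name: treatment
    parent: null
    source: "NCI"
    data_properties: [English name, nonpreferred term]
  - name: surgery
    parent: treatment
    source: "NCI"
    data_properties: []
  - name: medicine
    parent: treatment
    source: "NCI"
    data_properties: []
  - name: radiotherapy
    parent: treatment
    source: "NCI"
    data_properties: []
relations:
  - label: TeCD
    definition: "Test is conducted to investigate the disease."
    coarse_category: "Test-disease relation"
    head: [test]
    tail: [disease]
    structural: false
  - label: TeRD
    definition: "Test reveals the disease."
    coarse_category: "Test-disease relation"
    head: [test]
    tail: [disease]
    structural: false
  - label: TeRS
    definition: "Test reveals the symptoms and signs."
    coarse_category: "Test-clinical finding relation"
    head: [test]
    tail: [clinical finding]
    structural: false
  - label: TeAS
    definition: "Test is administered for the symptoms and signs."
    coarse_category: "Test-clinical finding relation"
    head: [test]
    tail: [clinical finding]
    structural: false
  - label: TrAD
    definition: "Treatment is administered for the disease."
    coarse_category: "Treatment-disease relation"
    head: [treatment]
    tail: [disease]
    structural: false
  - label: TrCD
    definition: "Treatment causes the disease."
    coarse_category: "Treatment-disease relation"
    head: [treatment]
    tail: [disease]
    structural: false
  - label: TrAS
    definition: "Treatment is administered for the symptoms and signs."
    coarse_category: "Treatment-clinical finding relation"
    head: [treatment]
    tail: [clinical finding]
    structural: false
  - label: TrCS
    definition: "Treatment causes the symptoms and signs."
    coarse_category: "Treatment-clinical finding relation"
    head: [treatment]
    tail: [clinical finding]
    structural: false
  - label: DCS
    definition: "Disease causes symptoms and signs."
    coarse_category: "Disease-clinical finding relation"
    head: [disease]
    tail: [clinical finding]
    structural: false
  - label: SID
    definition: "Symptoms and signs indicate the disease."
    coarse_category: "Disease-clinical finding relation"
    head: [clinical finding]
    tail: [disease]
    structural: false
  - label: CLAS
    definition: "Cancer disease type"
    coarse_category: "Disease-disease type relation"
    head: [disease]
    tail: [disease type]
    structural: false
  - label: LOCI
    definition: "Symptoms and signs are located in the body structure."
    coarse_category: "Clinical finding-body structure relation"
    head: [clinical finding, disease]
    tail: [body structure]
    structural: false
  - label: has_a
    definition: "The patient has a certain disease, clinical finding, test, or treatment."
    coarse_category: "Patient-disease, clinical finding, test, and treatment relation"
    head: [patient]
    tail: [disease, clinical finding, test, treatment]
    structural: false
  - label: attribute_of
    definition: "Properties of the entity"
    coarse_category: "Structural relation"
    head: ["*"]
    tail: ["*"]
    structural: true
  - label: instance_of
    definition: "Relation between a concept and its entities."
    coarse_category: "Structural relation"
    head: ["*"]
    tail: ["*"]
    structural: true
  - label: is_a
    definition: "Relation between a concept and its hyponym."
    coarse_category: "Structural relation"
    head: ["*"]
    tail: ["*"]
    structural: true
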