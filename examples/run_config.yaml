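# Full-pipeline run on a synthetic database sized for a quick demonstration.
# Omitting `drugs` under `simulate:` uses the default study configuration
# (antiresorptive vs comparator drugs over the 13 osteonecrosis-query terms)
# with the listed overrides.
simulate:
  n_cases: 20000
  missingness: {sex: 0.03, age: 0.07, height: 0.2, weight: 0.2}
seed: 11
event_terms: [osteonecrosis of the jaw]
min_reports: 10
drug_classes:
  zoledronate: BP
  alendronate: BP
  risedronate: BP
  denosumab: RANKL inhibitor
  prednisolone: Corticosteroid
  sunitinib: Tyrosine kinase inhibitor
  letrozole: Aromatase inhibitor
  methotrexate: Antimetabolite
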