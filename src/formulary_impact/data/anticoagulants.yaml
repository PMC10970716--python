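name: anticoagulants
output_unit: thousands
notes:
  - >-
    Exclusion of a brand-name oral anticoagulant used for atrial fibrillation
    (AFib) and/or venous thromboembolism (VTE). Prevalence is the bound-wise
    sum of AFib (1%-2.9%) and VTE (0.4%-0.5%) published ranges: 1.4%-3.4%.
  - >-
    Adverse events compound serious cardiovascular events among discontinuers
    (45%-85%) with adverse events among switchers (2%-10% of the complement).
population:
  total: 333300000
  segments:
    - name: employer private insurance
      percent: 48.5%
    - name: small group private insurance
      percent: 6.1%
    - name: Medicare Part D
      percent: 14.7%
formularies:
  - name: CVS
    market_share: 33%
  - name: ESI
    market_share: 24%
indication:
  name: AFib/VTE
  prevalence:
    low: 1.4%
    high: 3.4%
  eligibility_factors: []
  calibration_factor: 1.0
outcome_models:
  - id: anticoagulant
    discontinuation:
      low: 17%
      high: 30%
    adverse_event_rule:
      type: coupled_compound
      event_given_discontinuation:
        low: 45%
        high: 85%
      event_given_switch:
        low: 2%
        high: 10%
share_groups:
  - group_id: anticoagulants
    normalization: within_group
    medications:
      - brand_name: Eliquis
        generic_name: apixaban
        share: 68.88%
        outcome_model_id: anticoagulant
      - brand_name: Xarelto
        generic_name: rivaroxaban
        share: 29.76%
        outcome_model_id: anticoagulant
      - brand_name: Pradaxa
        generic_name: dabigatran
        share: 1.31%
        outcome_model_id: anticoagulant
      - brand_name: Savaysa
        generic_name: edoxaban
        share: 0.06%
        outcome_model_id: anticoagulant
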