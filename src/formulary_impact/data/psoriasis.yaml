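name: psoriasis
output_unit: thousands
notes:
  - >-
    Exclusion of a brand-name or biosimilar antipsoriatic. All 19
    medications form one share group (one market); discontinuation differs
    by mechanism, so outcome models attach per medication: TNF inhibitors
    use the 6%-9% forced-switch discontinuation range, all other agents the
    9%-19% cross-class nonmedical-switching range. Adverse events are a flat
    15%-35% of those affected for every agent.
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
  name: psoriasis
  prevalence:
    low: 1.5%
    high: 3%
  eligibility_factors: []
  calibration_factor: 1.0
outcome_models:
  - id: tnf_inhibitor
    discontinuation:
      low: 6%
      high: 9%
    adverse_event_rule:
      type: flat_rate
      rate:
        low: 15%
        high: 35%
  - id: other_antipsoriatic
    discontinuation:
      low: 9%
      high: 19%
    adverse_event_rule:
      type: flat_rate
      rate:
        low: 15%
        high: 35%
share_groups:
  - group_id: antipsoriatics
    normalization: within_group
    medications:
      - brand_name: Humira
        generic_name: adalimumab
        share: 38.92%
        outcome_model_id: tnf_inhibitor
      - brand_name: Enbrel
        generic_name: etanercept
        share: 13.18%
        outcome_model_id: tnf_inhibitor
      - brand_name: Cimzia
        generic_name: certolizumab
        share: 2.50%
        outcome_model_id: tnf_inhibitor
      - brand_name: Simponi
        generic_name: golimumab
        share: 1.41%
        outcome_model_id: tnf_inhibitor
      - brand_name: Remicade
        generic_name: infliximab
        share: 0.52%
        outcome_model_id: tnf_inhibitor
      - brand_name: Inflectra
        generic_name: infliximab
        share: 0.30%
        outcome_model_id: tnf_inhibitor
      - brand_name: Renflexis
        generic_name: infliximab
        share: 0.03%
        outcome_model_id: tnf_inhibitor
      - brand_name: Avsola
        generic_name: infliximab
        share: 0.02%
        outcome_model_id: tnf_inhibitor
      - brand_name: Infliximab
        generic_name: infliximab
        share: 0.02%
        outcome_model_id: tnf_inhibitor
      - brand_name: Otezla
        generic_name: apremilast
        share: 8.55%
        outcome_model_id: other_antipsoriatic
      # The published table prints "Cosentyx (ustekinumab)"; Cosentyx is
      # secukinumab (the reference table reproduces the printed label and
      # carries the erratum note).
      - brand_name: Cosentyx
        generic_name: secukinumab
        share: 7.30%
        outcome_model_id: other_antipsoriatic
      - brand_name: Stelara
        generic_name: ustekinumab
        share: 6.38%
        outcome_model_id: other_antipsoriatic
      - brand_name: Taltz
        generic_name: ixekizumab
        share: 6.17%
        outcome_model_id: other_antipsoriatic
      - brand_name: Xeljanz
        generic_name: tofacitinib
        share: 5.24%
        outcome_model_id: other_antipsoriatic
      - brand_name: Tremfya
        generic_name: guselkumab
        share: 3.46%
        outcome_model_id: other_antipsoriatic
      - brand_name: Rinvoq
        generic_name: upadacitinib
        share: 3.23%
        outcome_model_id: other_antipsoriatic
      - brand_name: Skyrizi
        generic_name: risankizumab
        share: 2.63%
        outcome_model_id: other_antipsoriatic
      - brand_name: Siliq
        generic_name: brodalumab
        share: 0.07%
        outcome_model_id: other_antipsoriatic
      - brand_name: Ilumya
        generic_name: tildrakizumab
        share: 0.06%
        outcome_model_id: other_antipsoriatic
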