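name: migraine
output_unit: thousands
notes:
  - >-
    Exclusion of a CGRP-blocking migraine preventive. The two share groups
    (monoclonal antibodies and gepants) are alternative partitions of the
    SAME eligible pool, not halves of it: per-group affected counts each sum
    to the full pool.
  - >-
    The published affected pools are ~0.837x what covered lives x prevalence
    x eligibility x formulary share yields; the residual multiplier
    (documented in an unavailable supplementary source list) is stored
    explicitly as calibration_factor and can be overridden or set to 1.
  - >-
    Unused annotation, kept for the record: among patients on preventive
    treatment, only 40% continue older non-CGRP medicines after 6 months.
    This figure plays no identifiable role in the published per-medication
    counts and enters no computation here.
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
  name: migraine (preventive-eligible)
  prevalence:
    low: 9.5%
    high: 11.6%
  eligibility_factors:
    - label: more than 3 attacks per month
      fraction: 33.3%
  calibration_factor: 0.8374
  calibration_provenance: calibrated_to_published_counts
outcome_models:
  - id: cgrp_preventive
    discontinuation:
      low: 9%
      high: 19%
    adverse_event_rule:
      type: flat_rate
      rate:
        low: 50%
        high: 50%
share_groups:
  - group_id: mabs
    normalization: within_group
    medications:
      - brand_name: Emgality
        generic_name: galcanezumab
        share: 42.56%
        outcome_model_id: cgrp_preventive
      - brand_name: Aimovig
        generic_name: erenumab
        share: 36.91%
        outcome_model_id: cgrp_preventive
      - brand_name: Ajovy
        generic_name: fremanezumab
        share: 20.49%
        outcome_model_id: cgrp_preventive
      - brand_name: Vyepti
        generic_name: eptinezumab
        share: 0.04%
        outcome_model_id: cgrp_preventive
  - group_id: gepants
    normalization: within_group
    medications:
      - brand_name: Nurtec
        generic_name: rimegepant
        share: 79.89%
        outcome_model_id: cgrp_preventive
      - brand_name: Qulipta
        generic_name: atogepant
        share: 20.11%
        outcome_model_id: cgrp_preventive
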