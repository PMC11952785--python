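# The shipped data-driven Sepsis SOFA score: seven organ domains, each a
# single biomarker banded at four thresholds (sub-score 0-4).
#
# inequality "ge": sub-score k is reached when value >= t_k (higher-worse).
# inequality "lt": sub-score k is reached when value <  t_k (lower-worse).
name: sepsis_sofa
map_adjustment_beta: 200.0
gcs_policy: set_max_15
neq_table: neq_default
components:
  - domain: liver
    concept_id: ast
    unit: IU/L
    inequality: ge
    thresholds: [45, 50, 195, 225]
  - domain: renal
    concept_id: bun
    unit: mg/dL
    inequality: ge
    thresholds: [15, 20, 25, 35]
  - domain: cns
    concept_id: gcs
    unit: points
    inequality: lt
    thresholds: [12, 8, 7, 6]
  - domain: metabolic
    concept_id: lactate
    unit: mmol/L
    inequality: ge
    thresholds: [1, 4, 6, 7]
  - domain: cardiovascular
    concept_id: map_adjusted
    unit: mmHg
    inequality: lt
    thresholds: [80, 40, 20, 5]
  - domain: respiratory
    concept_id: pf_ratio
    unit: mmHg
    inequality: lt
    thresholds: [350, 150, 100, 50]
  - domain: coagulation
    concept_id: platelets
    unit: 10^9/L
    inequality: lt
    thresholds: [70, 60, 40, 30]
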