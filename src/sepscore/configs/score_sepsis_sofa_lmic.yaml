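# LMIC variant of the Sepsis SOFA score: blood-gas-dependent markers are
# replaced by alternatives that need no blood gas machine — lactate by serum
# bicarbonate and the PaO2/FiO2 ratio by the SpO2/FiO2 ratio.
name: sepsis_sofa_lmic
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
    concept_id: bicarbonate
    unit: mEq/L
    inequality: lt
    thresholds: [19, 17, 16, 10]
  - domain: cardiovascular
    concept_id: map_adjusted
    unit: mmHg
    inequality: lt
    thresholds: [80, 40, 20, 5]
  - domain: respiratory
    concept_id: sf_ratio
    unit: ratio
    inequality: lt
    thresholds: [400, 350, 300, 250]
  - domain: coagulation
    concept_id: platelets
    unit: 10^9/L
    inequality: lt
    thresholds: [70, 60, 40, 30]
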