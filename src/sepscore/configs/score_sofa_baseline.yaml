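# Baseline comparator: the classic 6-domain SOFA score.
#
# Thresholds are taken from the original SOFA publication (Vincent et al.,
# Intensive Care Med 1996) — they are external reference values, shipped as
# config so the comparator is auditable and swappable.  Simplifications
# relative to the bedside score: respiratory levels 3-4 do not require
# ventilatory support, and the renal domain uses creatinine only (no urine
# output).  The cardiovascular domain keeps the original dose-based banding
# (kind: sofa_cardiovascular): hypotension -> 1; dopamine <=5 -> 2;
# dopamine >5 or norepinephrine/epinephrine <=0.1 -> 3; dopamine >15 or
# norepinephrine/epinephrine >0.1 -> 4 (all ug/kg/min).
name: sofa_baseline
map_adjustment_beta: 0.0
gcs_policy: raw
neq_table: neq_default
components:
  - domain: respiratory
    concept_id: pf_ratio
    unit: mmHg
    inequality: lt
    thresholds: [400, 300, 200, 100]
  - domain: coagulation
    concept_id: platelets
    unit: 10^9/L
    inequality: lt
    thresholds: [150, 100, 50, 20]
  - domain: liver
    concept_id: bilirubin
    unit: mg/dL
    inequality: ge
    thresholds: [1.2, 2.0, 6.0, 12.0]
  - domain: cardiovascular
    concept_id: map
    unit: mmHg
    inequality: lt
    thresholds: [70, 70, 70, 70]
    kind: sofa_cardiovascular
  - domain: cns
    concept_id: gcs
    unit: points
    inequality: lt
    thresholds: [15, 13, 10, 6]
  - domain: renal
    concept_id: creatinine
    unit: mg/dL
    inequality: ge
    thresholds: [1.2, 2.0, 3.5, 5.0]
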