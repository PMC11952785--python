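# Default clinical concept dictionary.
#
# normal_value is the normal-range imputation target used when a stay has no
# observation of the concept inside the lookback window.  Every normal_value
# must fall in the zero band of every shipped score component that uses the
# concept (enforced at load time).
concepts:
  pf_ratio:
    name: PaO2-to-FiO2 ratio
    unit: mmHg
    worst_direction: lower_worse
    normal_value: 450.0
    requires_blood_gas: true
    domain: respiratory
  sf_ratio:
    name: SpO2-to-FiO2 ratio
    unit: ratio
    worst_direction: lower_worse
    normal_value: 460.0
    requires_blood_gas: false
    domain: respiratory
  map:
    name: mean arterial pressure
    unit: mmHg
    worst_direction: lower_worse
    normal_value: 85.0
    requires_blood_gas: false
    domain: cardiovascular
  map_adjusted:
    name: vasopressor-adjusted mean arterial pressure
    unit: mmHg
    worst_direction: lower_worse
    normal_value: 85.0
    requires_blood_gas: false
    domain: cardiovascular
  platelets:
    name: platelet count
    unit: 10^9/L
    worst_direction: lower_worse
    normal_value: 250.0
    requires_blood_gas: false
    domain: coagulation
  ast:
    name: aspartate aminotransferase
    unit: IU/L
    worst_direction: higher_worse
    normal_value: 25.0
    requires_blood_gas: false
    domain: liver
  bilirubin:
    name: total bilirubin
    unit: mg/dL
    worst_direction: higher_worse
    normal_value: 0.7
    requires_blood_gas: false
    domain: liver
  gcs:
    name: Glasgow Coma Scale (sedation-adjusted at feature time)
    unit: points
    worst_direction: lower_worse
    normal_value: 15.0
    requires_blood_gas: false
    domain: cns
  rass:
    name: Richmond Agitation-Sedation Scale
    unit: points
    worst_direction: lower_worse
    normal_value: 0.0
    requires_blood_gas: false
    domain: cns
  bun:
    name: blood urea nitrogen
    unit: mg/dL
    worst_direction: higher_worse
    normal_value: 12.0
    requires_blood_gas: false
    domain: renal
  creatinine:
    name: serum creatinine
    unit: mg/dL
    worst_direction: higher_worse
    normal_value: 0.9
    requires_blood_gas: false
    domain: renal
  lactate:
    name: arterial lactate
    unit: mmol/L
    worst_direction: higher_worse
    normal_value: 0.9
    requires_blood_gas: true
    domain: metabolic
  bicarbonate:
    name: serum bicarbonate
    unit: mEq/L
    worst_direction: lower_worse
    normal_value: 24.0
    requires_blood_gas: false
    domain: metabolic
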