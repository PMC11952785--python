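# Default norepinephrine-equivalence conversion table.
#
# Factors are multiplicative: NEQ (ug/kg/min) = rate x factor, summed over
# concurrently running vasopressor infusions.  Rates are expected in
# ug/kg/min for catecholamines and U/min for vasopressin.  The factors follow
# the commonly cited norepinephrine-equivalence literature and are fully
# overridable from a user config.
name: neq_default
factors:
  norepinephrine: 1.0
  epinephrine: 1.0
  dopamine: 0.01
  phenylephrine: 0.1
  vasopressin: 2.5
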