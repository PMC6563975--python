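# Mahabee-Gittens-style any-of rule for radiographic pneumonia risk.
# Only the rule form is shipped: the original regression coefficients were
# never made public, so the model is validated as "high risk iff any
# listed sign present".
name: mahabee
label: "Mahabee-Gittens (2005), any-of rule form"
form: rule_any_of
source: "published rule terms; regression coefficients unavailable"
derivation_prevalence: 0.086
predictors:
  - variable: age_months
    op: ge
    value: 12
  - variable: resp_rate
    op: ge
    value: 50
  - variable: spo2_pct
    op: le
    value: 96
  - variable: nasal_flaring
    op: is_true
    when: {variable: age_months, op: lt, value: 12}
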