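# Van den Bruel pneumonia rule: high risk iff dyspnoea or the clinician's
# gestalt that "something is wrong".
name: vandenbruel
label: "Van den Bruel (2007), pneumonia rule"
form: rule_tree
source: "published classification-tree terms"
derivation_prevalence: 0.004
predictors:
  - variable: dyspnoea
    op: is_true
  - variable: something_wrong
    op: is_true
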