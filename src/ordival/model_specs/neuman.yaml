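# Neuman decision tree, first split only: in an all-febrile ED population
# the history-of-fever split is uninformative, leaving oxygen saturation
# <=92% as the single high/low discriminator. The cutoff and comparator are
# configuration (the source material prints both <=92 and <92; the table
# form <=92 is shipped).
name: neuman
label: "Neuman (2011), first tree split"
form: rule_tree
source: "published decision-tree first split"
derivation_prevalence: 0.164
predictors:
  - variable: spo2_pct
    op: le
    value: 92
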