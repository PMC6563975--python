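# Pre-specified mapping of ED working-diagnosis codes to the first-step
# class of the ordinal reference standard. Total over the codes emitted by
# the synthetic cohort generator; extend for other code dialects.
pneumonia: unknown
lrti: unknown
bacterial_pneumonia: bacterial_syndrome
empyema: bacterial_syndrome
bronchiolitis: viral_syndrome
viral_wheeze: viral_syndrome
uri: viral_syndrome
croup: viral_syndrome
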