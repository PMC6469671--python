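patient_id,rx_date,drug_concept,n_issues
F001,2008-04-01,interferon_beta,2
F001,2008-10-01,glatiramer,1
F003,2004-01-01,anticonvulsant,1
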