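patient_id,obs_date,kind,value
F001,2007-01-01,bmi,27.5
F004,2010-06-15,smoking,current
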