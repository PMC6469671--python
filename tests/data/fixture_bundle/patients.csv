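patient_id,sex,birth_date,geography,dialect
F001,F,1970-01-15,G001,CLAIMS_DOD
F002,M,1980-06-01,G001,CLAIMS_DOD
F003,F,1955-03-10,G002,CLAIMS_DOD
F004,F,1970-02-20,G001,CLAIMS_DOD
F005,M,1990-12-05,G002,CLAIMS_DOD
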