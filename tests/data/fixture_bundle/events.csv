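patient_id,event_date,concept,setting
F001,2008-03-01,ms,outpatient
F001,2008-03-01,ms,outpatient
F001,2008-06-10,ms,outpatient
F001,2009-01-05,ms,outpatient
F001,2007-11-20,optic_neuritis,outpatient
F002,2010-02-02,demyelinating_disease,outpatient
F003,2001-04-01,epilepsy,outpatient
F003,2002-04-01,epilepsy,outpatient
F003,2003-04-01,epilepsy,outpatient
F003,2004-04-01,epilepsy,outpatient
F003,2005-04-01,epilepsy,outpatient
F005,2012-05-05,urinary_infection,inpatient
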