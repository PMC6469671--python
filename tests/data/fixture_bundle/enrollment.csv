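patient_id,start_date,end_date
F001,2005-01-01,2015-12-31
F002,2008-01-01,2012-06-30
F002,2012-07-01,2014-01-01
F003,2000-05-01,2010-05-01
F004,2006-01-01,2016-01-01
F005,2010-01-01,2013-01-01
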