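patient_id	sex	age_years	fh_grade	bcva_logmar_re	bcva_logmar_le	iris_transillumination	nystagmus	misrouting	strabismus	fundus_pigmentation_grade	skin_hair_hypopigmentation
P1	F	8	3	0.2	0.2	N	N	Y	Y	0	Y
P2	M	12	3	0.2	0.3	N	N	Y	N	1	Y
P3	M	13	2	0.3	0.3	N	N	Y	Y	1	Y
P4	F	14	2	0.2	0.2	N	N	Y	N	1	Y
P5	F	17	2	0.2	0.3	N	N	Y	N	1	Y
P6	M	19	3	0.3	0.2	N	N	Y	N	1	Y
P7	M	10	2	0.1	0.1	N	N	Y	Y	0	Y
P8	M	39	2	0	0.1	N	N	Y	Y	0	Y
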