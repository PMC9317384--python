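name	gene	chrom	pos	ref	alt	hgvs_c	hgvs_p	consequence	maf_1000g	maf_evs	maf_dbsnp	maf_in_house	gnomad_hom_or_hemi	predictor_polyphen2	predictor_sift	predictor_mutation_taster	predictor_mutation_assessor	predictor_fathmm	predictor_fathmm_mkl	clinvar_or_hgmd_pathogenic	splice_predicted_damaging	acmg_class
Met1Val	TYR	chr11	88911121	A	G	c.1A>G	p.Met1Val	start_loss	0.00002			0.0003	0	damaging	damaging	damaging	missing	missing	damaging	Y	N	P
Gly47Asp	TYR	chr11	88911260	G	A	c.140G>A	p.Gly47Asp	missense		0.00001		0	0	damaging	damaging	damaging	damaging	benign	damaging	Y	N	P
Arg77Gln	TYR	chr11	88911350	G	A	c.230G>A	p.Arg77Gln	missense	0.00004	0.00002	0.00004	0.0003	0	damaging	damaging	damaging	damaging	damaging	damaging	Y	N	P
Met96Asnfs*73	TYR	chr11	88911406	A	AA	c.286dupA	p.Met96Asnfs*73	frameshift				0	0	missing	missing	damaging	missing	missing	missing	Y	N	P
Gly109Arg	TYR	chr11	88911445	G	A	c.325G>A	p.Gly109Arg	missense	0.00002			0	0	damaging	damaging	damaging	damaging	damaging	damaging	Y	N	P
Pro152Arg	TYR	chr11	88911575	C	G	c.455C>G	p.Pro152Arg	missense				0	0	damaging	damaging	damaging	damaging	damaging	damaging	N	N	P
Ser192Tyr	TYR	chr11	88911695	C	A	c.575C>A	p.Ser192Tyr	missense	0.249	0.243	0.254	0.24	18123	benign	damaging	benign	benign	benign	benign	N	N	B
Cys247Arg	TYR	chr11	88911859	T	C	c.739T>C	p.Cys247Arg	missense				0	0	damaging	damaging	damaging	damaging	damaging	damaging	Y	N	P
Arg402Gln	TYR	chr11	89017961	G	A	c.1205G>A	p.Arg402Gln	missense	0.17	0.176	0.172	0.165	9205	benign	damaging	benign	damaging	benign	benign	N	N	B
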