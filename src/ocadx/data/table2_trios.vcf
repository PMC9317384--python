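##fileformat=VCFv4.2
##FILTER=<ID=PASS,Description="All filters passed">
##contig=<ID=chr11,length=135086622>
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">
##INFO=<ID=PNAME,Number=1,Type=String,Description="Protein-level variant name">
#CHROM	POS	ID	REF	ALT	QUAL	FILTER	INFO	FORMAT	P1	P1_F	P1_M	P2	P2_F	P2_M	P3	P3_F	P3_M	F45_F	F45_M	P4	P5	P6	P6_F	P6_M	P7	P7_M	P8
chr11	88911121	Met1Val	A	G	.	.	GENE=TYR;PNAME=Met1Val	GT	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	0/1	0/0	0/1	./.	./.	./.
chr11	88911260	Gly47Asp	G	A	.	.	GENE=TYR;PNAME=Gly47Asp	GT	./.	./.	./.	./.	./.	./.	./.	./.	./.	0/0	0/1	0/1	0/1	./.	./.	./.	./.	./.	./.
chr11	88911350	Arg77Gln	G	A	.	.	GENE=TYR;PNAME=Arg77Gln	GT	0/1	0/1	0/0	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.
chr11	88911406	Met96Asnfs*73	A	AA	.	.	GENE=TYR;PNAME=Met96Asnfs*73	GT	./.	./.	./.	./.	./.	./.	0/1	0/0	0/1	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.
chr11	88911445	Gly109Arg	G	A	.	.	GENE=TYR;PNAME=Gly109Arg	GT	./.	./.	./.	./.	./.	./.	0/1	0/1	0/0	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.
chr11	88911575	Pro152Arg	C	G	.	.	GENE=TYR;PNAME=Pro152Arg	GT	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	0/1	0/0	0/1
chr11	88911695	Ser192Tyr	C	A	.	.	GENE=TYR;PNAME=Ser192Tyr	GT	1/1	1/1	0/1	0/1	0/1	0/0	./.	./.	./.	1/1	0/0	0/1	0/1	0/1	1/1	0/1	0/1	1/1	0/1
chr11	88911859	Cys247Arg	T	C	.	.	GENE=TYR;PNAME=Cys247Arg	GT	./.	./.	./.	0/1	0/0	0/1	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.	./.
chr11	89017961	Arg402Gln	G	A	.	.	GENE=TYR;PNAME=Arg402Gln	GT	0/1	0/0	1/1	1/1	1/1	0/1	./.	./.	./.	0/1	0/1	0/1	0/1	1/1	0/1	0/1	1/1	0/1	1/1
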