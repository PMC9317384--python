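F1	P1	P1_F	P1_M	2	2
F1	P1_F	0	0	1	1
F1	P1_M	0	0	2	1
F2	P2	P2_F	P2_M	1	2
F2	P2_F	0	0	1	1
F2	P2_M	0	0	2	1
F3	P3	P3_F	P3_M	1	2
F3	P3_F	0	0	1	1
F3	P3_M	0	0	2	1
F45	P4	F45_F	F45_M	2	2
F45	P5	F45_F	F45_M	2	2
F45	F45_F	0	0	1	1
F45	F45_M	0	0	2	1
F6	P6	P6_F	P6_M	1	2
F6	P6_F	0	0	1	1
F6	P6_M	0	0	2	1
F78	P7	P8	P7_M	1	2
F78	P8	0	0	1	2
F78	P7_M	0	0	2	1
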