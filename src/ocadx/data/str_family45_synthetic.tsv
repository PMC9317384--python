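individual	marker	allele1	allele2
F45_F	D11S4197	150	154
F45_F	D11S4162	201	205
F45_F	D11S4076	98	102
F45_F	D11S1392	174	174
F45_F	D11S4174	133	137
F45_F	D11S987	220	224
F45_F	D11S4151	161	165
F45_F	D11S912	88	92
F45_F	D11S1358	143	147
F45_M	D11S4197	158	162
F45_M	D11S4162	209	213
F45_M	D11S4076	106	110
F45_M	D11S1392	178	182
F45_M	D11S4174	141	145
F45_M	D11S987	228	232
F45_M	D11S4151	161	169
F45_M	D11S912	96	100
F45_M	D11S1358	151	155
P4	D11S4197	150	158
P4	D11S4162	201	209
P4	D11S4076	98	106
P4	D11S1392	174	178
P4	D11S4174	133	141
P4	D11S987	220	228
P4	D11S4151	161	161
P4	D11S912	88	96
P4	D11S1358	143	151
P5	D11S4197	150	158
P5	D11S4162	201	209
P5	D11S4076	98	106
P5	D11S1392	174	178
P5	D11S4174	133	141
P5	D11S987	220	228
P5	D11S4151	161	161
P5	D11S912	88	96
P5	D11S1358	143	151
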