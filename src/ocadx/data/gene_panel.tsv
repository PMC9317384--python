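gene	inheritance
TYR	AR
OCA2	AR
TYRP1	AR
SLC45A2	AR
SLC38A8	AR
DCT	AR
PAX6	AD
GPR143	XL
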