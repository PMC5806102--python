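gene_a	gene_b	coefficient
ACOT7	MIR6756	-0.038007046
CES1	RAB11FIP4	0.024780097
IPMK	RBPMS2	-0.190466701
NES	RPS27L	0.043310157
NES	TPMT	0.010844818
PBX3	TNFRSF11A	0.048826825
TMEM245	TNFRSF11A	0.014605079
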