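# Undirected interaction skeleton for the fixture (demo disease-network input).
IL1B	IL1R1
IL1R1	AKT1
AKT1	SRC
SRC	PTK2
PTK2	NFKB1
VEGFA	KDR
KDR	SRC
VEGFA	RAF1
RAF1	MAPK1
MAPK1	RELA
TNF	TNFRSF1A
TNFRSF1A	NFKB1
TNFRSF1A	NFKB2
TNFRSF1A	RELB
PTGS1	PTGS2
AHR	ARNT
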