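ANGIOGENESIS	Angiogenesis	VEGFA	KDR	RAF1	MAPK1	SRC	PTGS2
INFLAMMATORY_RESPONSE	Inflammatory response	IL1B	IL1R1	TNF	TNFRSF1A	PTGS1	PTGS2	NFKB1
IMMUNE_RESPONSE	Immune response	IL1B	TNF	RELA	RELB	NFKB1	NFKB2	AHR
NFKB_ACTIVITY	NF-kB activity	NFKB1	NFKB2	RELA	RELB
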