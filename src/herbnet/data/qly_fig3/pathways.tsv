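# Curated rheumatoid-arthritis signalling model: TNF-, IL1B- and VEGFA-induced
# NF-kB activation, with the NFKB1/NFKB2/RELA/RELB transcription-factor complex
# declared as a feedback loop. Columns: source  target  pathway.
IL1B	IL1R1	IL1B
IL1R1	AKT1	IL1B
AKT1	SRC	IL1B
SRC	PTK2	IL1B
PTK2	NFKB1	IL1B
VEGFA	KDR	VEGFA
KDR	SRC	VEGFA
VEGFA	RAF1	VEGFA
RAF1	MAPK1	VEGFA
MAPK1	RELA	VEGFA
TNF	TNFRSF1A	TNF
TNFRSF1A	NFKB1	TNF
TNFRSF1A	NFKB2	TNF
TNFRSF1A	RELB	TNF
!loop	NFKB1	NFKB2	RELA	RELB
!sink	NFKB1	NFKB2	RELA	RELB
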