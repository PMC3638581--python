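# Literature-reported targets of QLY ingredients. One (ingredient, gene) row
# per interaction. The five major ingredients carry the targets named in the
# published QLY mechanism description; Xanthohumol and ferulic acid carry the
# off-target PTGS1 story.
Matrine	IL1R1
Kurarinone	AKT1
Kurarinone	PTK2
Kurarinone	NFKB1
Sinomenine	NFKB1
Sinomenine	SRC
Berberine	KDR
Diosgenin	NFKB2
Diosgenin	RAF1
Xanthohumol	PTGS1
Xanthohumol	AHR
Ferulic_acid	PTGS1
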