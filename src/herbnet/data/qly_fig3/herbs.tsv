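# Herb of origin for each fixture ingredient; major = 1 marks the five major
# ingredients used in the synergy analysis.
Matrine	Ku-Shen	1
Kurarinone	Ku-Shen	1
Sinomenine	Qing-Feng-Teng	1
Berberine	Huang-Bai	1
Diosgenin	Bi-Xie	1
Xanthohumol	Ku-Shen	0
Ferulic_acid	Huang-Bai	0
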