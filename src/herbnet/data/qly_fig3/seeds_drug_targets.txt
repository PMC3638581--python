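# Targets of approved anti-rheumatic drugs (demo seed list)
TNF
PTGS1
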