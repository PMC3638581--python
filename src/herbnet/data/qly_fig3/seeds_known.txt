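# Known rheumatoid-arthritis genes (demo seed list)
TNF
IL1B
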