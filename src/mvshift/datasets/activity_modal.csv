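150,0,0
4,146,0
9,0,141
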