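150,0,0,0,0,0,0
0,31,44,41,34,0,0
0,0,0,0,0,24,126
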