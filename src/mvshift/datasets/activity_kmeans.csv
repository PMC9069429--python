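0,0,0,58,64,0,28
0,0,83,0,0,67,0
67,83,0,0,0,0,0
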