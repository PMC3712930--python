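row,col,mean,sd
U4,U4,0.70,0.28
U4,U5,0.66,0.24
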