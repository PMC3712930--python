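row,col,mean,sd
U4,S2,0.61,0.17
U4,S3,0.61,0.18
U4,S4,0.67,0.21
U5,S2,0.68,0.06
U5,S3,0.66,0.19
U5,S4,0.62,0.23
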