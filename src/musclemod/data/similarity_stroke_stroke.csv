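row,col,mean,sd
S2,S2,0.50,0.48
S2,S3,0.45,0.21
S2,S4,0.55,0.30
S3,S3,0.45,0.21
S3,S4,0.57,0.18
S4,S4,0.65,0.22
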