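muscle,THE,FDI,HTH,EDC,FDS,ECR/U,FCR/U
THE,1,0.33,0.10,0.16,0.32,0.56,0.25
FDI,0.33,1,0.13,0.15,0.36,0.14,0.24
HTH,0.10,0.13,1,0.10,0.31,0.28,0.37
EDC,0.16,0.15,0.10,1,0.07,0.60,0.21
FDS,0.32,0.36,0.31,0.07,1,0.25,0.66
ECR/U,0.56,0.14,0.28,0.60,0.25,1,0.27
FCR/U,0.25,0.24,0.37,0.21,0.66,0.27,1
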