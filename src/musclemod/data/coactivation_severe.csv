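muscle,THE,FDI,HTH,EDC,FDS,ECR/U,FCR/U
THE,1,0.61,0.56,0.52,0.40,0.57,0.45
FDI,0.61,1,0.65,0.70,0.63,0.67,0.62
HTH,0.56,0.65,1,0.56,0.47,0.59,0.50
EDC,0.52,0.70,0.56,1,0.54,0.76,0.58
FDS,0.40,0.63,0.47,0.54,1,0.57,0.56
ECR/U,0.57,0.67,0.59,0.76,0.57,1,0.53
FCR/U,0.45,0.62,0.50,0.58,0.56,0.53,1
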