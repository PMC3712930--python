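muscle,THE,FDI,HTH,EDC,FDS,ECR/U,FCR/U
THE,1,0.64,0.15,0.03,0.16,0.06,-0.07
FDI,0.64,1,-0.08,-0.20,0.20,-0.17,-0.08
HTH,0.15,-0.08,1,0.42,0.11,0.31,0.34
EDC,0.03,-0.20,0.42,1,0.25,0.57,0.23
FDS,0.16,0.20,0.11,0.25,1,0.18,0.49
ECR/U,0.06,-0.17,0.31,0.57,0.18,1,-0.02
FCR/U,-0.07,-0.08,0.34,0.23,0.49,-0.02,1
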