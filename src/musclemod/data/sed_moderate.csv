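task,WE,WF,FE,LP,PG,TP
WE,23.0,54.3,54.3,45.7,58.3,45.7
WF,54.3,28.4,34.8,45.8,53.9,40.2
FE,54.3,34.8,24.6,53.0,56.4,47.0
LP,45.7,45.8,53.0,23.8,41.3,18.8
PG,58.3,53.9,56.4,41.3,24.9,40.0
TP,45.7,40.2,47.0,18.8,40.0,22.9
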