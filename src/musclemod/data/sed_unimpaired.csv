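task,WE,WF,FE,LP,PG,TP
WE,18.9,41.1,48.0,71.2,54.2,59.8
WF,41.1,12.1,41.5,81.3,57.9,64.6
FE,48.0,41.5,17.0,73.6,51.8,60.7
LP,71.2,81.3,73.6,17.1,51.9,33.6
PG,54.2,57.9,51.8,51.9,19.8,42.1
TP,59.8,64.6,60.7,33.6,42.1,18.4
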