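task,WE,WF,FE,LP,PG,TP
WE,23.2,27.7,22.5,31.2,48.3,34.0
WF,27.7,25.0,19.5,29.9,41.7,32.7
FE,22.5,19.5,17.1,21.4,48.9,25.9
LP,31.2,29.9,21.4,24.3,35.4,8.1
PG,48.3,41.7,48.9,35.4,37.3,31.7
TP,34.0,32.7,25.9,8.1,31.7,25.9
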