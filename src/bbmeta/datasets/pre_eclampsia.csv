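study_id,events_trt,n_trt,events_ctl,n_ctl
weseley,14,131,14,136
flowers,21,385,17,134
menzies,14,57,24,48
fallis,6,38,18,40
cuadros,12,1011,35,760
landesman,138,1370,175,1336
krans,15,506,20,524
tervila,6,108,2,103
campbell,65,153,40,102
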