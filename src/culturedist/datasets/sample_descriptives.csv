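variable,mean,sd,n
IPSMR,51.1,9.8,133
IEMR,15.8,3.6,133
self_stigma,40.9,10.1,133
perceived_stigma,19.1,4.1,133
log_cultural_distance,-0.55,0.59,133
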