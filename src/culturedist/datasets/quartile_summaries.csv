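scale,quartile,mean,sd
IPSMR,1,52.8,4.0
IPSMR,2,55.0,6.6
IPSMR,3,54.2,8.3
IPSMR,4,41.4,11.4
IEMR,1,15.9,1.9
IEMR,2,17.0,2.5
IEMR,3,16.5,2.9
IEMR,4,13.4,4.7
self_stigma,1,39.1,9.7
self_stigma,2,43.9,2.5
self_stigma,3,43.2,10.1
self_stigma,4,37.6,10.9
perceived_stigma,1,18.8,3.9
perceived_stigma,2,19.6,3.8
perceived_stigma,3,19.5,4.2
perceived_stigma,4,18.5,4.3
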