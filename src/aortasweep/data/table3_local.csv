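subject,group,d_local_mean_e3,d_local_sd_e3,strain_mean,strain_sd
V1,healthy,63,7.9,0.23,0.03
V2,healthy,65,15,0.24,0.05
V3,healthy,105,23,0.28,0.05
V4,healthy,77,20,0.24,0.05
V5,healthy,104,24,0.25,0.05
V6,healthy,90,16,0.30,0.04
V7,healthy,67,6.5,0.25,0.02
V8,healthy,83,20,0.29,0.06
V9,healthy,60,13,0.23,0.05
V10,healthy,89,27,0.31,0.08
B1,aaa,27,20,0.13,0.09
B2,aaa,59,31,0.16,0.08
B3,aaa,45,19,0.16,0.08
B4,aaa,42,28,0.18,0.10
B5,aaa,60,60,0.22,0.18
B6,aaa,27,5.7,0.12,0.02
B7,aaa,23,12,0.13,0.07
B8,aaa,24,15,0.14,0.08
B9,aaa,21,13,0.14,0.07
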