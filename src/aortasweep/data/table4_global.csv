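subject,group,v_ed_ml,v_es_ml,c_global_ml_kpa,c_decimals,d_global_e3
V1,healthy,3.65,5.51,0.23,2,63
V2,healthy,12.2,18.7,0.78,2,64
V3,healthy,5.16,8.47,0.53,2,103
V4,healthy,10.3,15.3,0.71,2,69
V5,healthy,10.4,16.2,1.06,2,102
V6,healthy,3.75,6.56,0.34,2,90
V7,healthy,4.12,6.64,0.30,2,73
V8,healthy,6.37,10.5,0.52,2,82
V9,healthy,6.67,10.2,0.47,2,70
V10,healthy,3.09,5.20,0.24,2,79
B1,aaa,76,95,1.9,1,25
B2,aaa,40,50,1.0,1,25
B3,aaa,101,139,5.0,1,49
B4,aaa,33,45,1.2,1,37
B5,aaa,24,31,0.8,1,35
B6,aaa,30,38,0.8,1,28
B7,aaa,92,112,1.8,1,20
B8,aaa,18,23,0.4,1,22
B9,aaa,95,122,1.9,1,20
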