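subject,group,age_years,sex,dmax_mm,p_dia_mmhg,p_sys_mmhg
V1,healthy,25,M,,68,115
V2,healthy,27,M,,79,126
V3,healthy,25,F,,78,110
V4,healthy,28,M,,81,118
V5,healthy,29,F,,81,107
V6,healthy,26,M,,60,110
V7,healthy,25,M,,69,118
V8,healthy,24,F,,64,110
V9,healthy,26,F,,57,102
V10,healthy,25,F,,55,108
A1,aaa_ct,75,F,52,,
A2,aaa_ct,80,M,55,93,163
A3,aaa_ct,84,M,57,,
A4,aaa_ct,73,M,56,,
A5,aaa_ct,73,M,54,,
A6,aaa_ct,79,M,56,,
A7,aaa_ct,72,M,86,,
A8,aaa_ct,76,M,60,,
A9,aaa_ct,69,M,51,94,180
B1,aaa_bp,90,F,52,96,152
B2,aaa_bp,78,F,39,71,102
B3,aaa_bp,72,M,52,68,112
B4,aaa_bp,58,M,41,78,135
B5,aaa_bp,74,M,40,91,136
B6,aaa_bp,74,M,45,87,141
B7,aaa_bp,80,M,55,93,163
B8,aaa_bp,83,M,48,87,165
B9,aaa_bp,69,M,51,94,180
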