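group,trial,slope_ul_per_ul
nhp,C1-a,2.86
nhp,C1-b,3.90
nhp,C1-c,3.07
nhp,C1-d,4.61
nhp,C2-a,2.67
nhp,C2-b,3.05
nhp,CT-a,3.07
agar,1,3.03
agar,2,2.69
agar,3,2.72
agar,4,4.74
agar,5,4.11
agar,6,4.67
agar,7,4.23
agar,8,3.10
agar,9,4.81
agar,10,3.82
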