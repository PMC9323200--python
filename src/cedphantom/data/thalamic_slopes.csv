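group,trial,slope_ul_per_ul
nhp,T1-a,3.48
nhp,T2-a,3.59
nhp,T2-b,3.30
nhp,CT-a,6.38
agar,1,2.63
agar,2,3.71
agar,3,4.02
agar,4,2.66
agar,5,3.17
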