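q,D,N_x,kbar,s2
1,48,81,0.46,0.51
2,14,33,0.50,0.58
3,14,19,0.93,1.46
4,5,5,3.80,1.20
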