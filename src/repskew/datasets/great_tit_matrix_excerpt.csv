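id,age_1,age_2,age_3,age_4
1,0,0,NA,NA
2,1,1,0,NA
3,0,NA,NA,NA
5,1,NA,NA,NA
6,0,NA,2,3
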