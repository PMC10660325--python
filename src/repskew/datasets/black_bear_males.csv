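age,v,l,kbar,s2
1,0.639,1.000,0.000,NA
2,0.559,NA,0.027,0.026
3,0.670,NA,0.030,0.032
4,0.670,NA,0.030,0.033
5,0.670,NA,0.062,0.069
6,0.670,NA,0.121,0.166
7,0.670,NA,0.156,0.321
8,0.670,NA,0.196,0.329
9,0.670,NA,0.238,0.354
10,0.670,NA,0.377,0.454
11+,0.000,0.042,0.122,0.191
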