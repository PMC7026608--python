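res_i,atom_i,res_j,atom_j,class
2,H6,1,H1',m
3,H6,2,H1',m
4,H6,3,H1',m
6,H6,5,H1',m
8,H8,9,H6,m
11,H8,10,H1',m
11,H8,12,H6,m
12,H6,11,H1',m
14,H8,13,H1',m
14,H8,14,H1',s
14,H8,15,H6,l
15,H6,15,H1',s
17,H2,16,H1',m
17,H8,16,H1',l
17,H8,16,H8,m
17,H8,18,H8,m
18,H8,19,H6,m
19,H6,18,H1',m
20,H6,19,H1',m
22,H6,21,H1',m
25,H6,24,H1',m
26,H8,25,H6,m
29,H8,28,H1',m
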