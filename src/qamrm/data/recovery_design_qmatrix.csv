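item,a1,a2,a3
1,1,0,0
2,0,1,0
3,0,0,1
4,1,1,0
5,1,0,1
6,0,1,1
7,1,1,1
8,1,0,0
9,0,1,0
10,0,0,1
11,1,1,0
12,1,0,1
13,0,1,1
14,1,1,1
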