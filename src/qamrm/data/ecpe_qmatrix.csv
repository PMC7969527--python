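item,morphosyntactic,cohesive,lexical
1,1,1,0
2,0,1,0
3,1,0,1
4,0,0,1
5,0,0,1
6,0,0,1
7,1,0,1
8,0,1,0
9,0,0,1
10,1,0,0
11,1,0,1
12,1,0,1
13,1,0,0
14,1,0,0
15,0,0,1
16,1,0,1
17,0,1,1
18,0,0,1
19,0,0,1
20,1,0,1
21,1,0,1
22,0,0,1
23,0,1,0
24,0,1,0
25,1,0,0
26,0,0,1
27,1,0,0
28,0,0,1
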