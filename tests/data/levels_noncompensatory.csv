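item,g000,g001,g010,g011,g100,g101,g110,g111
1,2,2,2,2,1,1,1,1
2,2,2,1,1,2,2,1,1
3,2,1,2,1,2,1,2,1
4,2,2,2,2,2,2,1,1
5,2,2,2,2,2,1,2,1
6,2,2,2,1,2,2,2,1
7,2,2,2,2,2,2,2,1
8,2,2,2,2,1,1,1,1
9,2,2,1,1,2,2,1,1
10,2,1,2,1,2,1,2,1
11,2,2,2,2,2,2,1,1
12,2,2,2,2,2,1,2,1
13,2,2,2,1,2,2,2,1
14,2,2,2,2,2,2,2,1
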