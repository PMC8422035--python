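item,retrieving_information,straightforward_inference,integrated_inference
1,1,0,0
2,1,1,0
3,0,1,0
4,1,1,0
5,1,1,0
6,0,0,1
7,1,0,0
8,1,0,0
9,1,1,0
10,0,1,0
11,0,1,0
12,1,1,0
13,1,0,0
14,1,0,0
15,1,1,0
16,0,1,0
17,1,1,0
18,0,0,1
19,1,1,0
20,1,0,0
21,0,0,1
22,0,0,1
23,0,0,1
24,0,0,1
25,0,0,1
26,0,0,1
27,0,0,1
28,0,1,1
29,0,1,0
30,0,0,1
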