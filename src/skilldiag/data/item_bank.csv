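item,a_1,a_2,a_3,d,c
1,1.10,0.00,0.00,2.51,0.23
2,0.61,0.72,0.00,0.54,0.17
3,0.00,0.98,0.00,1.12,0.15
4,0.85,0.77,0.00,0.49,0.29
5,0.70,0.58,0.00,-0.42,0.10
6,0.00,0.00,1.30,-0.53,0.56
7,1.38,0.00,0.00,0.48,0.53
8,1.32,0.00,0.00,-0.15,0.44
9,1.05,1.02,0.00,2.09,0.34
10,0.00,1.34,0.00,0.93,0.28
11,0.00,0.90,0.00,0.87,0.21
12,0.68,0.85,0.00,2.54,0.38
13,1.33,0.00,0.00,2.73,0.13
14,1.32,0.00,0.00,1.44,0.14
15,1.40,1.08,0.00,1.10,0.32
16,0.00,2.03,0.00,4.89,0.17
17,1.08,1.55,0.00,5.01,0.15
18,0.00,0.00,0.70,1.95,0.23
19,0.56,0.56,0.00,2.58,0.22
20,1.40,0.00,0.00,5.01,0.23
21,0.00,0.00,0.98,1.79,0.20
22,0.00,0.00,0.87,1.44,0.12
23,0.00,0.00,1.38,2.33,0.19
24,0.00,0.00,1.52,2.43,0.18
25,0.00,0.00,0.50,-0.30,0.16
26,0.00,0.00,1.60,3.17,0.17
27,0.00,0.00,1.07,0.94,0.07
28,0.00,0.93,1.04,1.10,0.23
29,0.00,0.53,0.00,0.23,0.23
30,0.00,0.00,0.69,0.58,0.13
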