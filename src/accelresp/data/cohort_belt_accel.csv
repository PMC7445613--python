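subject,belt,accel
1,15,17
2,18,18
3,16,16
4,16,17
5,17,17
6,18,18
7,16,15
8,18,18
9,17,19
10,18,20
11,17,18
12,15,16
13,17,18
14,16,17
15,18,20
16,16,16
17,15,15
18,15,17
19,16,16
20,16,17
21,17,16
22,16,15
23,17,16
24,16,16
25,15,16
26,16,17
27,15,15
28,18,18
29,17,16
30,17,17
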