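subject,shoulder,foot
1,17,17
2,18,19
3,15,15
4,16,17
5,16,15
6,16,16
7,18,18
8,17,17
9,18,18
10,17,17
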