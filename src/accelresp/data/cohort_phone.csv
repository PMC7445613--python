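subject,phone1,phone2
1,18,18
2,17,18
3,18,18
4,18,19
5,17,17
6,17,17
7,18,18
8,18,18
9,18,18
10,19,19
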