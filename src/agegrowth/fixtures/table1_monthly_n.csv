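month,count
1,18
2,33
3,7
4,3
5,29
6,10
7,42
8,37
9,20
10,14
11,10
12,22
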