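length_bin_lower,age_group,count
42,2,1
44,2,2
48,1,2
48,2,1
48,3,1
50,2,1
50,3,3
50,5,1
52,2,5
52,4,5
54,2,1
54,3,4
54,4,5
54,6,1
56,2,1
56,3,1
56,4,10
56,5,3
58,3,4
58,4,6
58,5,3
58,6,3
58,7,1
60,3,3
60,4,7
60,5,9
60,6,3
62,3,1
62,4,3
62,5,12
62,6,6
64,3,1
64,4,3
64,5,7
64,6,2
64,7,2
64,8,1
66,5,3
66,6,5
66,7,7
66,8,3
66,9,1
68,4,1
68,6,3
68,7,5
68,8,1
68,9,3
68,10,1
70,6,3
70,7,5
70,8,2
70,9,5
70,10,6
70,11,1
72,7,4
72,8,1
72,9,6
72,10,8
72,11,2
72,12,1
74,8,3
74,9,4
74,10,8
74,11,5
74,12,3
76,8,2
76,9,2
76,10,1
76,11,2
76,12,2
78,10,2
78,11,4
78,12,2
82,13,1
82,14,1
84,14,1
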