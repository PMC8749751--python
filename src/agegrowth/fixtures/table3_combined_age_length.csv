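length_bin_lower,age_group,count
16,9,1
18,0,3
20,0,10
22,0,59
24,0,78
26,0,67
26,1,4
28,0,14
28,1,19
30,0,9
30,1,37
30,2,2
32,0,5
32,1,48
32,2,3
34,1,63
34,2,10
36,1,31
36,2,25
36,3,2
38,1,27
38,2,34
38,3,5
40,1,6
40,2,48
40,3,7
40,4,1
42,1,7
42,2,49
42,3,16
42,4,2
44,1,2
44,2,25
44,3,31
44,4,5
46,1,1
46,2,23
46,3,41
46,4,8
46,5,2
48,1,2
48,2,16
48,3,44
48,4,19
48,5,4
50,2,3
50,3,38
50,4,32
50,5,7
52,2,8
52,3,22
52,4,45
52,5,11
52,6,4
54,2,1
54,3,13
54,4,33
54,5,24
54,6,8
56,2,1
56,3,9
56,4,40
56,5,31
56,6,8
56,7,3
58,3,6
58,4,21
58,5,32
58,6,25
58,7,7
58,8,1
60,3,3
60,4,13
60,5,34
60,6,19
60,7,12
60,8,2
62,3,1
62,4,4
62,5,23
62,6,26
62,7,19
62,8,6
62,9,1
64,3,1
64,4,3
64,5,14
64,6,22
64,7,21
64,8,18
64,9,1
66,5,3
66,6,16
66,7,23
66,8,15
66,9,12
66,10,1
68,4,1
68,6,7
68,7,12
68,8,21
68,9,15
68,10,5
70,6,3
70,7,11
70,8,14
70,9,17
70,10,14
70,11,3
72,7,5
72,8,5
72,9,16
72,10,12
72,11,5
72,12,1
74,8,3
74,9,8
74,10,12
74,11,7
74,12,4
76,8,2
76,9,2
76,10,4
76,11,4
76,12,3
78,10,2
78,11,5
78,12,3
78,13,1
82,12,1
82,13,1
82,14,1
84,13,1
84,14,1
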