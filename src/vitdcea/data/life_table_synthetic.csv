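age,annual_mortality_probability
0,0.004000
1,0.000300
2,0.000200
3,0.000200
4,0.000100
5,0.000100
6,0.000100
7,0.000100
8,0.000100
9,0.000100
10,0.000100
11,0.000100
12,0.000100
13,0.000100
14,0.000100
15,0.000100
16,0.000100
17,0.000101
18,0.000111
19,0.000122
20,0.000134
21,0.000147
22,0.000162
23,0.000178
24,0.000196
25,0.000215
26,0.000236
27,0.000260
28,0.000286
29,0.000314
30,0.000346
31,0.000380
32,0.000418
33,0.000460
34,0.000506
35,0.000556
36,0.000611
37,0.000672
38,0.000739
39,0.000813
40,0.000894
41,0.000983
42,0.001081
43,0.001189
44,0.001307
45,0.001438
46,0.001581
47,0.001738
48,0.001912
49,0.002102
50,0.002312
51,0.002542
52,0.002795
53,0.003074
54,0.003380
55,0.003717
56,0.004088
57,0.004495
58,0.004943
59,0.005436
60,0.005977
61,0.006573
62,0.007228
63,0.007948
64,0.008741
65,0.009612
66,0.010570
67,0.011623
68,0.012781
69,0.014055
70,0.015456
71,0.016996
72,0.018690
73,0.020552
74,0.022601
75,0.024853
76,0.027330
77,0.030053
78,0.033049
79,0.036342
80,0.039964
81,0.043947
82,0.048326
83,0.053143
84,0.058439
85,0.064263
86,0.070667
87,0.077709
88,0.085454
89,0.093970
90,0.103335
91,0.113633
92,0.124958
93,0.137411
94,0.151105
95,0.166164
96,0.182724
97,0.200934
98,0.220959
99,0.242979
100,0.267195
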