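# Synthetic stand-in background-utility norm for US males (source values
# unpublished). Piecewise constant by decade: 0.83 (65-74), 0.80 (75-84),
# 0.77 (85-94), 0.75 (95+). Calibrated jointly with life_table.csv.
age,utility
65,0.83
66,0.83
67,0.83
68,0.83
69,0.83
70,0.83
71,0.83
72,0.83
73,0.83
74,0.83
75,0.8
76,0.8
77,0.8
78,0.8
79,0.8
80,0.8
81,0.8
82,0.8
83,0.8
84,0.8
85,0.77
86,0.77
87,0.77
88,0.77
89,0.77
90,0.77
91,0.77
92,0.77
93,0.77
94,0.77
95,0.75
96,0.75
97,0.75
98,0.75
99,0.75
100,0.75
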