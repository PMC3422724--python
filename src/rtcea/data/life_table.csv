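# Synthetic stand-in life table (NOT SEER data; SEER values are unpublished).
# Gompertz annual hazard a*exp(b*(age-65)), a=0.034755945817, b=0.09,
# q(100) forced to 1. Calibrated jointly with background_utility.csv so the
# discounted quality-weight factor D = 8.375 at a 3% discount rate.
age,qx
65,0.034158894942219464
66,0.03731503718011853
67,0.04075659189419645
68,0.044508158186675306
69,0.04859621768885747
70,0.05304923092727987
71,0.057897728213724076
72,0.06317439209057818
73,0.06891412772091277
74,0.07515411687270501
75,0.08193385030155365
76,0.08929513238059583
77,0.09728205075792906
78,0.10594090264319644
79,0.11532006804546246
80,0.1254698189228135
81,0.1364420517916769
82,0.148289929928608
83,0.1610674199484844
84,0.17482870635655368
85,0.18962746677621434
86,0.20551599011747357
87,0.22254412018592362
88,0.24075800840301176
89,0.26019866173426576
90,0.2809002759767185
91,0.30288835066315833
92,0.3261775904573928
93,0.35076960950891156
94,0.37665047024116827
95,0.4037881068021034
96,0.4321297060593745
97,0.46159914542296276
98,0.49209461631986207
99,0.5234865936004108
100,1.0
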