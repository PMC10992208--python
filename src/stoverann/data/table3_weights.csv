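j,IW_j1,IW_j2,IW_j3,IW_j4,IW_j5,IW_j6,b1_j,LW_1j,LW_2j,b2_k
1,0.4211,0.5806,0.1236,0.2909,0.1691,0.5445,-0.0095,0.0448,0.4378,-0.0381
2,0.3931,0.1473,0.2595,0.4280,0.2980,0.4272,-0.0393,0.3972,0.4253,-0.0051
3,0.3056,0.1740,0.3713,0.1522,0.1229,0.1367,-0.0287,0.0356,0.2299,
4,0.5184,0.0507,0.2491,0.0508,0.3027,0.4435,-0.0379,0.6842,0.1607,
5,0.3112,0.4807,0.7085,0.2731,0.3305,0.6146,0.0394,0.2159,0.0281,
6,0.1854,0.5232,0.0776,0.4782,0.3439,0.1783,-0.0306,0.1249,0.4419,
7,0.0370,0.2334,0.0454,0.3650,0.2354,0.4857,0.0372,0.3608,0.0639,
8,0.2985,0.2512,0.3173,0.1907,0.1834,0.5006,0.0361,0.5057,0.4299,
9,0.3070,0.4097,0.0005,0.5172,0.3769,0.2365,-0.0184,0.0140,0.3469,
10,0.3136,0.2505,0.1438,0.0805,0.0552,0.1178,-0.0320,0.2159,0.6152,
11,0.6273,0.0770,0.3091,0.3422,0.3044,0.3722,0.0394,0.6076,0.3147,
12,0.5133,0.5409,0.0001,0.4964,0.2515,0.1423,0.0371,0.5611,0.2426,
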