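patient_id,age,tumor_length_cm,pixel_vol_d1,pixel_vol_d2,pixel_diff,trad_vol_d1,trad_vol_d2,trad_diff
1,46,1.8,0.676,0.665,0.011,0.531,0.560,0.029
2,31,2.5,1.503,1.558,0.055,1.152,1.574,0.422
3,30,2.5,1.526,1.541,0.015,1.210,1.059,0.151
4,20,2.4,4.040,4.040,0.000,3.466,3.091,0.375
5,19,2.1,2.535,2.580,0.045,1.716,2.443,0.727
6,19,1.4,0.171,0.172,0.001,0.117,0.102,0.015
7,46,3.3,10.174,10.261,0.087,12.078,12.708,0.630
8,36,1.0,0.218,0.208,0.010,0.177,0.165,0.012
9,29,2.2,0.758,0.760,0.002,0.692,0.750,0.058
10,40,1.0,0.330,0.358,0.028,0.246,0.243,0.003
11,32,1.6,0.582,0.578,0.004,0.788,0.733,0.055
12,51,1.2,0.320,0.325,0.005,0.263,0.290,0.027
13,37,1.8,0.730,0.719,0.011,0.552,0.619,0.067
14,28,1.4,0.246,0.245,0.001,0.165,0.184,0.019
15,41,1.6,0.444,0.441,0.003,0.367,0.436,0.069
16,65,1.3,0.571,0.586,0.015,0.444,0.542,0.098
17,35,1.8,1.384,1.328,0.056,1.154,1.211,0.057
18,25,2.2,1.487,1.451,0.036,1.403,1.505,0.102
19,51,2.6,2.017,2.022,0.005,1.926,1.905,0.021
20,37,1.3,0.228,0.227,0.001,0.275,0.302,0.027
21,21,1.2,0.347,0.329,0.018,0.421,0.388,0.033
22,28,1.3,0.619,0.610,0.009,0.611,0.569,0.042
23,18,2.3,1.508,1.518,0.010,0.724,1.355,0.631
24,36,1.9,0.447,0.449,0.002,0.431,0.490,0.059
25,45,1.4,0.362,0.376,0.014,0.227,0.243,0.016
26,55,1.2,0.232,0.232,0.000,0.174,0.204,0.030
27,27,1.1,0.225,0.260,0.035,0.148,0.147,0.001
28,25,1.4,0.301,0.311,0.010,0.479,0.534,0.055
29,37,2.9,2.538,2.483,0.055,2.257,2.418,0.161
30,47,1.8,1.286,1.384,0.098,0.931,1.496,0.565
31,25,4.9,10.606,10.848,0.242,10.023,11.749,1.726
32,57,4.1,4.501,4.099,0.402,8.992,7.965,1.027
33,28,2.8,4.550,4.598,0.048,3.480,3.825,0.345
34,26,1.9,0.290,0.302,0.012,0.252,0.496,0.244
35,59,3.1,3.299,3.358,0.059,3.512,3.009,0.503
36,52,4.4,8.838,8.748,0.090,9.523,10.309,0.786
37,32,2.0,1.077,1.090,0.013,1.228,1.043,0.185
38,25,3.8,2.954,2.984,0.030,3.456,4.033,0.577
39,59,2.9,1.164,1.198,0.034,1.774,1.983,0.209
40,55,2.6,3.114,3.076,0.038,2.891,4.288,1.397
41,27,2.2,1.351,1.344,0.007,1.665,2.013,0.348
42,51,3.0,4.466,4.421,0.045,3.889,4.980,1.091
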