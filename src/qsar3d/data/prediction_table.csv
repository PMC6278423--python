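id,pic50,comfa,comsia,topomer,role
1,4.770,4.570,4.530,4.815,train
2,6.013,6.239,6.323,6.311,test
3,8.301,8.158,8.314,8.476,train
4,2.620,2.646,2.429,2.562,train
5,4.215,4.191,4.181,4.057,train
6,5.824,5.662,5.910,6.222,train
7,8.097,8.260,8.081,8.378,test
8,8.000,8.161,8.067,8.212,train
9,8.523,8.600,8.472,8.389,train
10,7.721,7.575,7.782,8.172,test
11,7.770,7.582,7.511,7.740,train
12,4.678,4.807,4.869,4.889,test
13,6.081,6.302,6.614,7.054,train
14,5.194,5.107,5.303,4.946,test
15,5.051,5.222,5.137,5.209,train
16,6.658,7.002,6.808,6.972,train
17,7.721,7.288,6.971,7.064,train
18,7.620,7.152,7.458,6.995,train
19,7.409,7.460,7.690,6.909,train
20,7.284,7.335,7.271,7.006,test
21,7.357,7.481,7.260,6.700,train
22,6.237,6.547,6.313,6.442,train
23,5.854,5.948,5.936,5.651,train
24,5.174,5.142,5.264,5.746,train
25,4.350,4.449,4.528,4.619,train
26,4.519,4.435,4.527,4.561,test
27,4.558,4.466,4.592,4.554,train
28,4.046,4.064,4.163,4.314,train
29,4.770,4.750,4.643,4.529,train
30,4.740,4.707,4.634,4.597,train
31,3.983,3.751,3.971,3.723,train
32,4.629,4.775,4.849,4.599,train
33,4.400,4.424,4.336,4.606,train
34,5.061,5.317,5.197,5.401,train
35,6.292,6.200,6.234,5.857,train
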