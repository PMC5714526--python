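# Benchmark dataset: radial dose function g_L(r) of the 169Yb Model M42 HDR
# source — FLUKA values with the independent MCNP5 characterisation of the
# same model and the published percent difference between the two.
# Values preserved exactly as printed.
r_cm,g_fluka,g_mcnp5,difference_pct
0.5,0.965,0.945,2.07
1,1.000,1.000,0.00
2,1.071,1.081,-0.93
3,1.129,1.131,-0.18
4,1.167,1.158,0.77
5,1.195,1.168,2.26
6,1.210,1.165,3.72
7,1.194,1.151,3.60
8,1.159,1.128,2.67
9,1.122,1.098,2.14
10,1.086,1.062,2.21
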