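# Benchmark dataset: FLUKA-calculated dose rate in water around the 169Yb
# Model M42 HDR source, cGy/h/mCi, polar grid (r in cm across, theta in deg down).
# Source along z, origin at the source centre, cable side at theta = 180 deg.
# Values preserved exactly as printed (3 decimals).
theta_deg,0.5,1,2,3,4,5,6,7,8,9,10
0,4.544,0.968,0.199,0.084,0.063,0.036,0.029,0.023,0.017,0.015,0.010
10,4.353,0.808,0.212,0.108,0.055,0.038,0.032,0.024,0.017,0.013,0.011
20,5.013,0.996,0.290,0.132,0.071,0.047,0.032,0.025,0.018,0.014,0.011
30,4.905,1.129,0.294,0.133,0.080,0.047,0.038,0.027,0.020,0.015,0.011
40,5.000,1.184,0.304,0.152,0.081,0.053,0.038,0.027,0.021,0.015,0.012
50,4.881,1.216,0.323,0.150,0.085,0.054,0.037,0.027,0.020,0.016,0.012
60,4.559,1.225,0.326,0.151,0.088,0.057,0.039,0.029,0.021,0.016,0.013
70,4.462,1.238,0.337,0.160,0.090,0.058,0.041,0.029,0.021,0.016,0.013
80,4.387,1.241,0.334,0.159,0.092,0.060,0.041,0.029,0.022,0.017,0.014
90,4.399,1.229,0.336,0.158,0.092,0.060,0.042,0.030,0.022,0.017,0.013
100,4.324,1.229,0.341,0.158,0.091,0.057,0.042,0.030,0.022,0.016,0.013
110,4.465,1.241,0.331,0.156,0.088,0.057,0.040,0.028,0.021,0.016,0.013
120,4.607,1.217,0.320,0.158,0.088,0.057,0.039,0.028,0.021,0.017,0.013
130,4.844,1.227,0.326,0.148,0.086,0.054,0.039,0.027,0.020,0.017,0.012
140,5.100,1.167,0.311,0.144,0.084,0.051,0.038,0.028,0.020,0.015,0.012
150,4.977,1.098,0.287,0.135,0.076,0.050,0.036,0.026,0.019,0.015,0.012
160,5.018,0.945,0.271,0.120,0.073,0.047,0.032,0.025,0.017,0.013,0.011
170,3.902,0.754,0.220,0.100,0.057,0.045,0.029,0.020,0.017,0.013,0.010
180,3.748,0.943,0.133,0.100,0.061,0.040,0.026,0.022,0.016,0.012,0.010
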