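# Benchmark dataset: 2D anisotropy function F(r, theta) of the 169Yb Model
# M42 HDR source (FLUKA), r in cm across, theta in deg down, cable at 180 deg.
# Values preserved exactly as printed (3 decimals).
theta_deg,0.5,1,2,3,4,5,6,7,8,9,10
0,0.595,0.696,0.574,0.526,0.688,0.605,0.692,0.765,0.778,0.860,0.770
10,0.590,0.584,0.612,0.680,0.601,0.634,0.750,0.802,0.747,0.764,0.842
20,0.738,0.728,0.841,0.825,0.768,0.775,0.765,0.837,0.811,0.841,0.852
30,0.800,0.840,0.857,0.836,0.874,0.785,0.897,0.875,0.893,0.875,0.863
40,0.899,0.900,0.889,0.959,0.883,0.886,0.913,0.897,0.939,0.883,0.942
50,0.954,0.945,0.951,0.947,0.927,0.905,0.891,0.902,0.900,0.960,0.924
60,0.952,0.970,0.965,0.952,0.954,0.952,0.934,0.966,0.937,0.934,0.983
70,0.976,0.995,0.999,1.011,0.977,0.961,0.963,0.962,0.956,0.943,1.011
80,0.987,1.006,0.992,1.008,1.007,1.000,0.985,0.946,0.964,1.008,1.021
90,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000,1.000
100,0.973,0.997,1.015,1.005,0.991,0.953,0.987,0.994,0.967,0.967,0.961
110,0.977,0.997,0.981,0.986,0.960,0.952,0.959,0.934,0.954,0.949,0.975
120,0.962,0.963,0.945,0.996,0.958,0.956,0.925,0.939,0.949,0.978,0.972
130,0.947,0.953,0.960,0.932,0.933,0.903,0.918,0.898,0.916,0.979,0.934
140,0.917,0.888,0.910,0.904,0.913,0.853,0.899,0.923,0.879,0.911,0.891
150,0.811,0.818,0.834,0.847,0.825,0.839,0.846,0.845,0.857,0.889,0.939
160,0.739,0.691,0.784,0.756,0.789,0.781,0.764,0.832,0.776,0.777,0.859
170,0.528,0.544,0.637,0.626,0.620,0.743,0.693,0.662,0.761,0.781,0.788
180,0.491,0.678,0.385,0.627,0.667,0.663,0.630,0.733,0.698,0.737,0.754
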