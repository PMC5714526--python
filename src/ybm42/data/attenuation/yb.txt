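# Yb (Z=70, A=173.045) photon mass interaction coefficients, 10-400 keV.
# Constructed tables: incoherent = free-electron Klein-Nishina;
# coherent = calibrated power-law surrogate; photoelectric anchored to
# standard attenuation compilations (water/air compounds exact at nodes);
# mu_en from the transfer decomposition with K-fluorescence escape.
# Columns: energy_keV  pe  incoherent  coherent  mu_en   (cm^2/g)
10  3.916481e+02  4.224233e-02  3.449206e+00  3.916489e+02
15  1.284237e+02  6.973653e-02  1.731267e+00  1.284256e+02
20  5.821884e+01  8.996517e-02  1.061618e+00  5.822208e+01
30  1.909029e+01  1.120264e-01  5.328599e-01  1.909612e+01
40  8.654282e+00  1.206704e-01  3.267512e-01  8.662353e+00
50  4.685204e+00  1.234829e-01  2.235992e-01  4.695170e+00
60  2.837789e+00  1.236643e-01  1.640069e-01  2.849368e+00
61.3259  2.672242e+00  1.235757e-01  1.580247e-01  2.684017e+00
61.3381  1.388802e+01  1.235748e-01  1.579710e-01  4.145782e+00
80  6.689627e+00  1.209251e-01  1.005695e-01  3.101444e+00
100  3.621591e+00  1.168886e-01  6.882072e-02  2.077548e+00
150  1.187540e+00  1.067871e-01  3.454332e-02  8.658688e-01
200  5.383527e-01  9.835967e-02  2.118206e-02  4.436724e-01
300  1.765289e-01  8.584605e-02  1.063195e-02  1.743283e-01
400  8.002661e-02  7.701573e-02  6.519544e-03  9.525390e-02
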