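# H (Z=1, A=1.008) photon mass interaction coefficients, 10-400 keV.
# Constructed tables: incoherent = free-electron Klein-Nishina;
# coherent = calibrated power-law surrogate; photoelectric anchored to
# standard attenuation compilations (water/air compounds exact at nodes);
# mu_en from the transfer decomposition with K-fluorescence escape.
# Columns: energy_keV  pe  incoherent  coherent  mu_en   (cm^2/g)
10  1.000000e-06  3.510451e-01  5.166567e-02  6.587879e-03
15  1.000000e-06  3.613114e-01  2.593265e-02  9.965870e-03
20  1.000000e-06  3.610825e-01  1.590197e-02  1.301814e-02
30  1.000000e-06  3.534293e-01  7.981709e-03  1.839309e-02
40  1.000000e-06  3.438242e-01  4.894407e-03  2.299648e-02
50  1.000000e-06  3.342603e-01  3.349292e-03  2.697842e-02
60  1.000000e-06  3.251593e-01  2.456659e-03  3.044542e-02
80  1.000000e-06  3.086102e-01  1.506430e-03  3.614803e-02
100  1.000000e-06  2.941203e-01  1.030866e-03  4.059059e-02
150  1.000000e-06  2.649193e-01  5.174244e-04  4.809994e-02
200  1.000000e-06  2.427921e-01  3.172861e-04  5.252960e-02
300  1.000000e-06  2.111423e-01  1.592560e-04  5.693644e-02
400  1.765079e-05  1.891847e-01  9.765625e-05  5.859427e-02
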