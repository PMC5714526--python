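# O (Z=8, A=15.999) photon mass interaction coefficients, 10-400 keV.
# Constructed tables: incoherent = free-electron Klein-Nishina;
# coherent = calibrated power-law surrogate; photoelectric anchored to
# standard attenuation compilations (water/air compounds exact at nodes);
# mu_en from the transfer decomposition with K-fluorescence escape.
# Columns: energy_keV  pe  incoherent  coherent  mu_en   (cm^2/g)
10  5.505358e+00  1.307520e-01  3.157677e-01  5.566098e+00
15  1.521492e+00  1.563814e-01  1.584939e-01  1.545864e+00
20  6.015240e-01  1.663383e-01  9.718891e-02  6.179958e-01
30  1.582606e-01  1.709007e-01  4.878222e-02  1.730002e-01
40  5.937361e-02  1.692482e-01  2.991340e-02  7.535929e-02
50  2.681530e-02  1.659314e-01  2.047004e-02  4.415165e-02
60  1.359278e-02  1.621605e-01  1.501449e-02  3.208327e-02
80  4.072689e-03  1.546204e-01  9.206927e-03  2.468760e-02
100  1.135995e-03  1.476778e-01  6.300394e-03  2.355359e-02
150  1.000000e-06  1.332997e-01  3.162369e-03  2.506211e-02
200  1.000000e-06  1.222572e-01  1.939174e-03  2.678976e-02
300  1.000000e-06  1.063768e-01  9.733333e-04  2.876801e-02
400  1.000000e-06  9.533211e-02  5.968507e-04  2.953875e-02
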