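# P (Z=15, A=30.974) photon mass interaction coefficients, 10-400 keV.
# Constructed tables: incoherent = free-electron Klein-Nishina;
# coherent = calibrated power-law surrogate; photoelectric anchored to
# standard attenuation compilations (water/air compounds exact at nodes);
# mu_en from the transfer decomposition with K-fluorescence escape.
# Columns: energy_keV  pe  incoherent  coherent  mu_en   (cm^2/g)
10  3.534222e+01  1.046159e-01  6.502286e-01  3.498185e+01
15  1.046591e+01  1.359658e-01  3.263705e-01  1.039813e+01
20  4.437926e+00  1.506475e-01  2.001313e-01  4.420607e+00
30  1.334766e+00  1.602656e-01  1.004523e-01  1.338544e+00
40  5.722576e-01  1.608845e-01  6.159764e-02  5.815511e-01
50  2.976189e-01  1.587689e-01  4.215189e-02  3.098225e-01
60  1.748069e-01  1.557261e-01  3.091782e-02  1.890887e-01
80  7.577545e-02  1.490313e-01  1.895890e-02  9.313415e-02
100  3.974731e-02  1.425845e-01  1.297377e-02  5.938370e-02
150  1.233716e-02  1.289224e-01  6.511948e-03  3.573597e-02
200  5.379200e-03  1.183136e-01  3.993145e-03  3.097386e-02
300  1.669649e-03  1.029898e-01  2.004287e-03  2.944073e-02
400  7.279938e-04  9.231064e-02  1.229034e-03  2.930964e-02
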