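# Mn (Z=25, A=54.938) photon mass interaction coefficients, 10-400 keV.
# Constructed tables: incoherent = free-electron Klein-Nishina;
# coherent = calibrated power-law surrogate; photoelectric anchored to
# standard attenuation compilations (water/air compounds exact at nodes);
# mu_en from the transfer decomposition with K-fluorescence escape.
# Columns: energy_keV  pe  incoherent  coherent  mu_en   (cm^2/g)
10  1.595115e+02  8.044050e-02  1.127867e+00  1.347233e+02
15  5.177263e+01  1.130019e-01  5.661123e-01  4.641175e+01
20  2.286501e+01  1.307270e-01  3.471417e-01  2.109299e+01
30  7.036796e+00  1.447317e-01  1.742415e-01  6.679797e+00
40  2.992630e+00  1.476890e-01  1.068454e-01  2.886236e+00
50  1.525274e+00  1.469303e-01  7.311538e-02  1.489724e+00
60  8.732766e-01  1.447700e-01  5.362911e-02  8.642120e-01
80  3.576324e-01  1.391877e-01  3.288552e-02  3.669878e-01
100  1.770175e-01  1.334567e-01  2.250390e-02  1.926840e-01
150  4.890238e-02  1.209315e-01  1.129543e-02  7.035213e-02
200  1.963070e-02  1.110653e-01  6.926387e-03  4.350739e-02
300  5.423122e-03  9.673337e-02  3.476575e-03  3.147961e-02
400  2.176984e-03  8.671963e-02  2.131846e-03  2.901923e-02
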