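# Ti (Z=22, A=47.867) photon mass interaction coefficients, 10-400 keV.
# Constructed tables: incoherent = free-electron Klein-Nishina;
# coherent = calibrated power-law surrogate; photoelectric anchored to
# standard attenuation compilations (water/air compounds exact at nodes);
# mu_en from the transfer decomposition with K-fluorescence escape.
# Columns: energy_keV  pe  incoherent  coherent  mu_en   (cm^2/g)
10  1.096371e+02  8.576054e-02  9.771388e-01  1.006137e+02
15  3.526146e+01  1.180848e-01  4.904572e-01  3.332964e+01
20  1.541422e+01  1.350276e-01  3.007497e-01  1.478466e+01
30  4.673197e+00  1.478467e-01  1.509559e-01  4.552663e+00
40  1.971264e+00  1.501694e-01  9.256659e-02  1.940740e+00
50  1.000603e+00  1.490530e-01  6.334426e-02  9.961591e-01
60  5.729676e-01  1.466703e-01  4.646213e-02  5.788394e-01
80  2.358821e-01  1.408272e-01  2.849071e-02  2.499498e-01
100  1.176597e-01  1.349439e-01  1.949648e-02  1.353138e-01
150  3.291175e-02  1.222023e-01  9.785908e-03  5.491829e-02
200  1.319167e-02  1.122076e-01  6.000746e-03  3.741373e-02
300  3.575333e-03  9.771270e-02  3.011966e-03  2.991418e-02
400  1.370358e-03  8.759270e-02  1.846946e-03  2.848857e-02
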