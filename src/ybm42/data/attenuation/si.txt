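# Si (Z=14, A=28.085) photon mass interaction coefficients, 10-400 keV.
# Constructed tables: incoherent = free-electron Klein-Nishina;
# coherent = calibrated power-law surrogate; photoelectric anchored to
# standard attenuation compilations (water/air compounds exact at nodes);
# mu_en from the transfer decomposition with K-fluorescence escape.
# Columns: energy_keV  pe  incoherent  coherent  mu_en   (cm^2/g)
10  3.316358e+01  1.102909e-01  6.161264e-01  3.293472e+01
15  9.880258e+00  1.419274e-01  3.092535e-01  9.838305e+00
20  4.120232e+00  1.564467e-01  1.896351e-01  4.111526e+00
30  1.175134e+00  1.656822e-01  9.518394e-02  1.181028e+00
40  4.751183e-01  1.660223e-01  5.836706e-02  4.853950e-01
50  2.332946e-01  1.636952e-01  3.994117e-02  2.461811e-01
60  1.297257e-01  1.604794e-01  2.929629e-02  1.446008e-01
80  5.085124e-02  1.535041e-01  1.796457e-02  6.878668e-02
100  2.437701e-02  1.468297e-01  1.229334e-02  4.462302e-02
150  6.363644e-03  1.327300e-01  6.170419e-03  3.045925e-02
200  2.453952e-03  1.217980e-01  3.783718e-03  2.880436e-02
300  6.406068e-04  1.060167e-01  1.899169e-03  2.922832e-02
400  2.470312e-04  9.502171e-02  1.164576e-03  2.966824e-02
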