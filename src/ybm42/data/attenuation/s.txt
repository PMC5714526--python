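# S (Z=16, A=32.06) photon mass interaction coefficients, 10-400 keV.
# Constructed tables: incoherent = free-electron Klein-Nishina;
# coherent = calibrated power-law surrogate; photoelectric anchored to
# standard attenuation compilations (water/air compounds exact at nodes);
# mu_en from the transfer decomposition with K-fluorescence escape.
# Columns: energy_keV  pe  incoherent  coherent  mu_en   (cm^2/g)
10  4.440801e+01  1.053545e-01  7.240407e-01  4.376241e+01
15  1.330381e+01  1.382223e-01  3.634192e-01  1.317829e+01
20  5.670368e+00  1.539089e-01  2.228497e-01  5.634573e+00
30  1.710397e+00  1.644598e-01  1.118554e-01  1.710642e+00
40  7.325550e-01  1.653869e-01  6.859003e-02  7.409457e-01
50  3.800149e-01  1.633531e-01  4.693686e-02  3.920905e-01
60  2.224831e-01  1.602998e-01  3.442753e-02  2.369511e-01
80  9.575209e-02  1.534833e-01  2.111106e-02  1.135548e-01
100  4.985902e-02  1.468776e-01  1.444651e-02  7.005591e-02
150  1.524962e-02  1.328345e-01  7.251166e-03  3.935232e-02
200  6.580007e-03  1.219136e-01  4.446436e-03  3.295149e-02
300  2.012527e-03  1.061296e-01  2.231808e-03  3.062987e-02
400  8.683783e-04  9.512682e-02  1.368551e-03  3.032186e-02
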