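# Cr (Z=24, A=51.996) photon mass interaction coefficients, 10-400 keV.
# Constructed tables: incoherent = free-electron Klein-Nishina;
# coherent = calibrated power-law surrogate; photoelectric anchored to
# standard attenuation compilations (water/air compounds exact at nodes);
# mu_en from the transfer decomposition with K-fluorescence escape.
# Columns: energy_keV  pe  incoherent  coherent  mu_en   (cm^2/g)
10  1.427259e+02  8.303749e-02  1.089325e+00  1.244824e+02
15  4.598631e+01  1.159024e-01  5.467669e-01  4.207047e+01
20  2.024360e+01  1.335777e-01  3.352790e-01  1.895452e+01
30  6.218619e+00  1.473536e-01  1.682873e-01  5.961306e+00
40  2.646381e+00  1.501354e-01  1.031942e-01  2.571849e+00
50  1.350979e+00  1.492506e-01  7.061685e-02  1.328485e+00
60  7.750665e-01  1.469930e-01  5.179648e-02  7.723162e-01
80  3.188575e-01  1.412629e-01  3.176175e-02  3.303083e-01
100  1.585586e-01  1.354184e-01  2.173489e-02  1.752199e-01
150  4.421267e-02  1.226836e-01  1.090943e-02  6.611041e-02
200  1.786574e-02  1.126662e-01  6.689696e-03  4.212714e-02
300  4.981704e-03  9.812254e-02  3.357772e-03  3.141965e-02
400  2.013040e-03  8.796337e-02  2.058995e-03  2.924241e-02
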