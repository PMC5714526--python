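# Fe (Z=26, A=55.845) photon mass interaction coefficients, 10-400 keV.
# Constructed tables: incoherent = free-electron Klein-Nishina;
# coherent = calibrated power-law surrogate; photoelectric anchored to
# standard attenuation compilations (water/air compounds exact at nodes);
# mu_en from the transfer decomposition with K-fluorescence escape.
# Columns: energy_keV  pe  incoherent  coherent  mu_en   (cm^2/g)
10  1.693096e+02  8.090254e-02  1.209538e+00  1.376853e+02
15  5.635854e+01  1.143580e-01  6.071060e-01  4.934345e+01
20  2.517494e+01  1.327826e-01  3.722791e-01  2.282848e+01
30  7.841611e+00  1.475304e-01  1.868588e-01  7.361036e+00
40  3.363646e+00  1.507713e-01  1.145823e-01  3.216654e+00
50  1.729480e+00  1.501097e-01  7.840985e-02  1.676985e+00
60  9.995219e-01  1.479656e-01  5.751253e-02  9.822585e-01
80  4.176112e-01  1.423220e-01  3.526685e-02  4.245303e-01
100  2.110766e-01  1.364899e-01  2.413346e-02  2.259699e-01
150  6.058112e-02  1.237055e-01  1.211336e-02  8.228678e-02
200  2.495079e-02  1.136213e-01  7.427944e-03  4.929997e-02
300  7.207033e-03  9.896464e-02  3.728323e-03  3.384841e-02
400  2.992238e-03  8.872154e-02  2.286218e-03  3.044882e-02
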