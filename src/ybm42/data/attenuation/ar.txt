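# Ar (Z=18, A=39.948) photon mass interaction coefficients, 10-400 keV.
# Constructed tables: incoherent = free-electron Klein-Nishina;
# coherent = calibrated power-law surrogate; photoelectric anchored to
# standard attenuation compilations (water/air compounds exact at nodes);
# mu_en from the transfer decomposition with K-fluorescence escape.
# Columns: energy_keV  pe  incoherent  coherent  mu_en   (cm^2/g)
10  5.757370e+01  9.104805e-02  7.529515e-01  5.592478e+01
15  1.761657e+01  1.215670e-01  3.779305e-01  1.728322e+01
20  7.579325e+00  1.366450e-01  2.317480e-01  7.475602e+00
30  2.298355e+00  1.472597e-01  1.163217e-01  2.284053e+00
40  9.825425e-01  1.485998e-01  7.132882e-02  9.854388e-01
50  5.073278e-01  1.470200e-01  4.881104e-02  5.162845e-01
60  2.952753e-01  1.444080e-01  3.580222e-02  3.073852e-01
80  1.254257e-01  1.383997e-01  2.195402e-02  1.411868e-01
100  6.444239e-02  1.325027e-01  1.502336e-02  8.254345e-02
150  1.918763e-02  1.198877e-01  7.540704e-03  4.091786e-02
200  8.122913e-03  1.100486e-01  4.623981e-03  3.192053e-02
300  2.418586e-03  9.581164e-02  2.320924e-03  2.825230e-02
400  1.023887e-03  8.588193e-02  1.423197e-03  2.761449e-02
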