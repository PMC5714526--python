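# Mo (Z=42, A=95.95) photon mass interaction coefficients, 10-400 keV.
# Constructed tables: incoherent = free-electron Klein-Nishina;
# coherent = calibrated power-law surrogate; photoelectric anchored to
# standard attenuation compilations (water/air compounds exact at nodes);
# mu_en from the transfer decomposition with K-fluorescence escape.
# Columns: energy_keV  pe  incoherent  coherent  mu_en   (cm^2/g)
10  1.010453e+02  6.051418e-02  2.021930e+00  1.010464e+02
15  3.117822e+01  9.233916e-02  1.014871e+00  3.118077e+01
19.998  1.354113e+01  1.125371e-01  6.224276e-01  1.354519e+01
20  8.799183e+01  1.125433e-01  6.223218e-01  8.799589e+01
20.002  8.796632e+01  1.125494e-01  6.222160e-01  3.704046e+01
30  2.715049e+01  1.313747e-01  3.123632e-01  1.667672e+01
40  1.178841e+01  1.372090e-01  1.915420e-01  8.384677e+00
50  6.171864e+00  1.381269e-01  1.310741e-01  4.753538e+00
60  3.637397e+00  1.370161e-01  9.614106e-02  2.948174e+00
80  1.579314e+00  1.326496e-01  5.895397e-02  1.366234e+00
100  8.268550e-01  1.276073e-01  4.034280e-02  7.487107e-01
150  2.551319e-01  1.160141e-01  2.024934e-02  2.564983e-01
200  1.107752e-01  1.066738e-01  1.241695e-02  1.274401e-01
300  3.418044e-02  9.298664e-02  6.232466e-03  5.793527e-02
400  1.484073e-02  8.338534e-02  3.821765e-03  4.022939e-02
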