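# Ni (Z=28, A=58.693) photon mass interaction coefficients, 10-400 keV.
# Constructed tables: incoherent = free-electron Klein-Nishina;
# coherent = calibrated power-law surrogate; photoelectric anchored to
# standard attenuation compilations (water/air compounds exact at nodes);
# mu_en from the transfer decomposition with K-fluorescence escape.
# Columns: energy_keV  pe  incoherent  coherent  mu_en   (cm^2/g)
10  2.368620e+02  8.020634e-02  1.354640e+00  1.762093e+02
15  7.845834e+01  1.147158e-01  6.799372e-01  6.506740e+01
20  3.496472e+01  1.341435e-01  4.169394e-01  3.049277e+01
30  1.081552e+01  1.500756e-01  2.092752e-01  9.900137e+00
40  4.591421e+00  1.538249e-01  1.283282e-01  4.307773e+00
50  2.329676e+00  1.533767e-01  8.781626e-02  2.222741e+00
60  1.326289e+00  1.513126e-01  6.441200e-02  1.283851e+00
80  5.363480e-01  1.456662e-01  3.949762e-02  5.362415e-01
100  2.620809e-01  1.397538e-01  2.702862e-02  2.746562e-01
150  7.055449e-02  1.267152e-01  1.356653e-02  9.235652e-02
200  2.780780e-02  1.164023e-01  8.319035e-03  5.263566e-02
300  7.486104e-03  1.013974e-01  4.175589e-03  3.476446e-02
400  2.950514e-03  9.090579e-02  2.560483e-03  3.107848e-02
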