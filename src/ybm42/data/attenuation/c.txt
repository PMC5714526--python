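# C (Z=6, A=12.011) photon mass interaction coefficients, 10-400 keV.
# Constructed tables: incoherent = free-electron Klein-Nishina;
# coherent = calibrated power-law surrogate; photoelectric anchored to
# standard attenuation compilations (water/air compounds exact at nodes);
# mu_en from the transfer decomposition with K-fluorescence escape.
# Columns: energy_keV  pe  incoherent  coherent  mu_en   (cm^2/g)
10  2.009749e+00  1.398854e-01  2.233655e-01  2.012374e+00
15  5.329505e-01  1.620352e-01  1.121143e-01  5.374194e-01
20  2.033684e-01  1.698828e-01  6.874880e-02  2.094927e-01
30  4.918125e-02  1.725115e-01  3.450722e-02  5.815857e-02
40  1.634918e-02  1.700909e-01  2.115993e-02  2.772512e-02
50  6.213054e-03  1.664070e-01  1.447995e-02  1.964340e-02
60  2.242375e-03  1.624368e-01  1.062084e-02  1.745121e-02
80  1.000000e-06  1.547034e-01  6.512731e-03  1.812117e-02
100  1.000000e-06  1.476769e-01  4.456728e-03  2.038090e-02
150  1.000000e-06  1.332270e-01  2.236974e-03  2.418978e-02
200  1.000000e-06  1.221674e-01  1.371719e-03  2.643219e-02
300  1.000000e-06  1.062843e-01  6.885096e-04  2.866103e-02
400  1.000000e-06  9.524466e-02  4.221960e-04  2.949128e-02
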