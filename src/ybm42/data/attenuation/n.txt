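# N (Z=7, A=14.007) photon mass interaction coefficients, 10-400 keV.
# Constructed tables: incoherent = free-electron Klein-Nishina;
# coherent = calibrated power-law surrogate; photoelectric anchored to
# standard attenuation compilations (water/air compounds exact at nodes);
# mu_en from the transfer decomposition with K-fluorescence escape.
# Columns: energy_keV  pe  incoherent  coherent  mu_en   (cm^2/g)
10  3.555962e+00  1.350862e-01  2.688643e-01  3.620219e+00
15  9.715528e-01  1.591035e-01  1.349516e-01  9.982197e-01
20  3.786275e-01  1.680521e-01  8.275269e-02  3.968627e-01
30  9.568928e-02  1.716766e-01  4.153622e-02  1.116093e-01
40  3.410530e-02  1.696487e-01  2.547013e-02  5.056292e-02
50  1.441086e-02  1.661520e-01  1.742947e-02  3.193725e-02
60  6.540062e-03  1.622835e-01  1.278427e-02  2.519428e-02
80  1.159841e-03  1.546489e-01  7.839352e-03  2.189225e-02
100  1.000000e-06  1.476655e-01  5.364548e-03  2.215022e-02
150  1.000000e-06  1.332532e-01  2.692638e-03  2.465775e-02
200  1.000000e-06  1.222031e-01  1.651133e-03  2.661031e-02
300  1.000000e-06  1.063227e-01  8.287566e-04  2.871322e-02
400  1.000000e-06  9.528137e-02  5.081959e-04  2.950690e-02
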