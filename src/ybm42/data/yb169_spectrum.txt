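# 169Yb photon emission spectrum (electron-capture decay to 169Tm, T1/2 = 32.02 d).
# Columns: energy_keV  photons_per_decay
# Lines: Tm K X-rays (Kalpha2, Kalpha1, Kbeta1', Kbeta2') followed by gamma rays,
# compiled from evaluated nuclear decay data (ENSDF-style intensities).
# Tm L X-rays (~7-10 keV) are omitted: they fall below the 10 keV transport cutoff
# and have sub-millimetre range in water.
# Intensity-weighted mean energy 93.3 keV; total yield 3.286 photons per decay.
49.772    0.5200
50.742    0.9180
57.450    0.2930
59.300    0.0810
63.1205   0.4405
93.614    0.02571
109.7799  0.1739
118.1897  0.0187
130.5230  0.1138
177.2130  0.2232
197.9675  0.3593
240.3000  0.0012
261.0770  0.0171
307.7358  0.1005
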