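# Principal Ir-192 photon emission lines >= 60 keV (gammas + K x-rays),
# intensities in photons per decay (NNDC-derived tabulation). Beta emissions are
# excluded: the collisional-KERMA estimator needs no electron transport.
energy_keV,intensity
61.49,0.012
63,0.0207
65.12,0.0263
66.83,0.0448
71.08,0.0024
71.41,0.0046
75.37,0.0053
75.75,0.0102
77.83,0.0036
136.34,0.002
176.98,0.0043
201.31,0.0047
205.79,0.0334
283.27,0.0027
295.96,0.2871
308.46,0.2968
316.51,0.8286
374.49,0.0073
416.47,0.0067
420.52,0.0007
468.07,0.4781
484.58,0.0319
489.06,0.0044
588.58,0.0452
604.41,0.0822
612.46,0.0534
884.54,0.0029
1061.48,0.0005
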