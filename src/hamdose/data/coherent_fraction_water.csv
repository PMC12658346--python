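# Approximate coherent (Rayleigh) fraction of the total attenuation
# coefficient of water; applied to all low-Z media when the optional
# Rayleigh channel is on.
energy_keV,coherent_fraction
10,0.115
15,0.105
20,0.09
30,0.066
40,0.052
50,0.042
60,0.035
80,0.026
100,0.02
150,0.013
200,0.009
300,0.006
400,0.004
500,0.003
600,0.0025
800,0.0018
1000,0.0014
1250,0.0011
1500,0.0009
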