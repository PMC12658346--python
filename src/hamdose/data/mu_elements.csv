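# Mass attenuation coefficients mu/rho (cm^2/g), total WITH coherent scattering,
# transcribed from the standard NIST elemental compilation (10-1500 keV).
element,energy_keV,mu_over_rho
H,10,0.3854
H,15,0.3764
H,20,0.3695
H,30,0.357
H,40,0.3458
H,50,0.3355
H,60,0.326
H,80,0.3091
H,100,0.2944
H,150,0.2651
H,200,0.2429
H,300,0.2112
H,400,0.1893
H,500,0.1729
H,600,0.1599
H,800,0.1405
H,1000,0.1263
H,1250,0.1129
H,1500,0.1027
C,10,2.373
C,15,0.8071
C,20,0.442
C,30,0.2562
C,40,0.2076
C,50,0.1871
C,60,0.1753
C,80,0.161
C,100,0.1514
C,150,0.1347
C,200,0.1229
C,300,0.1066
C,400,0.09546
C,500,0.08715
C,600,0.08058
C,800,0.07076
C,1000,0.06361
C,1250,0.0569
C,1500,0.05179
N,10,3.879
N,15,1.236
N,20,0.6178
N,30,0.3066
N,40,0.2288
N,50,0.198
N,60,0.1817
N,80,0.1639
N,100,0.1529
N,150,0.1353
N,200,0.1233
N,300,0.1068
N,400,0.09557
N,500,0.08719
N,600,0.08063
N,800,0.07081
N,1000,0.06364
N,1250,0.05693
N,1500,0.0518
O,10,5.952
O,15,1.836
O,20,0.8651
O,30,0.3779
O,40,0.2585
O,50,0.2132
O,60,0.1907
O,80,0.1678
O,100,0.1551
O,150,0.1361
O,200,0.1237
O,300,0.107
O,400,0.09566
O,500,0.08729
O,600,0.0807
O,800,0.07087
O,1000,0.06372
O,1250,0.05697
O,1500,0.05185
Si,10,33.89
Si,15,10.34
Si,20,4.464
Si,30,1.436
Si,40,0.7012
Si,50,0.4385
Si,60,0.3207
Si,80,0.2228
Si,100,0.1835
Si,150,0.1448
Si,200,0.1275
Si,300,0.1082
Si,400,0.09614
Si,500,0.08748
Si,600,0.08077
Si,800,0.07082
Si,1000,0.06361
Si,1250,0.05688
Si,1500,0.05183
Ar,10,62.66
Ar,15,19.83
Ar,20,8.629
Ar,30,2.697
Ar,40,1.228
Ar,50,0.7012
Ar,60,0.4664
Ar,80,0.276
Ar,100,0.2043
Ar,150,0.1427
Ar,200,0.1205
Ar,300,0.09953
Ar,400,0.08776
Ar,500,0.07958
Ar,600,0.07335
Ar,800,0.06419
Ar,1000,0.05762
Ar,1250,0.0515
Ar,1500,0.04695
Fe,10,170.6
Fe,15,57.08
Fe,20,25.68
Fe,30,8.176
Fe,40,3.629
Fe,50,1.958
Fe,60,1.205
Fe,80,0.5952
Fe,100,0.3717
Fe,150,0.1964
Fe,200,0.146
Fe,300,0.1099
Fe,400,0.094
Fe,500,0.08414
Fe,600,0.07704
Fe,800,0.06699
Fe,1000,0.05995
Fe,1250,0.0535
Fe,1500,0.04883
# Ir column is SYNTHETIC: photoelectric part Z^4.5-scaled from Pb with the
# K-edge relocated to 76.1 keV, plus Klein-Nishina incoherent scattering.
Ir,10,93.0486
Ir,15,73.91
Ir,20,44.7415
Ir,30,15.694
Ir,40,7.45129
Ir,50,4.19817
Ir,60,2.64669
Ir,76,2.61212
Ir,76.2,2.63739
Ir,80,3.15505
Ir,100,2.932
Ir,150,1.09157
Ir,200,0.566135
Ir,300,0.253149
Ir,400,0.160115
Ir,500,0.119792
Ir,600,0.09809
Ir,800,0.0749663
Ir,1000,0.0629028
Ir,1250,0.0544299
Ir,1500,0.0499265
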