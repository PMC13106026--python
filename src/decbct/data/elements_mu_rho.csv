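# Elemental mass attenuation coefficients mu/rho (cm^2/g), total with coherent
# scattering, NIST-style standard grid. Used with the mixture rule to build
# compound tables; log-log interpolated in energy.
energy_keV,H,C,N,O,F,Al,Ar,Ca
10,0.3854,2.373,3.879,5.952,8.205,26.23,62.05,93.41
15,0.3764,0.8071,1.236,1.836,2.492,7.955,19.62,29.56
20,0.3695,0.4420,0.6178,0.8651,1.133,3.441,8.629,12.76
30,0.3570,0.2562,0.3066,0.3779,0.4487,1.128,2.697,4.080
40,0.3458,0.2076,0.2288,0.2585,0.2828,0.5685,1.228,1.830
50,0.3355,0.1871,0.1980,0.2132,0.2214,0.3681,0.7012,1.019
60,0.3260,0.1753,0.1817,0.1907,0.1920,0.2778,0.4664,0.6578
80,0.3091,0.1610,0.1639,0.1678,0.1639,0.2018,0.2760,0.3656
100,0.2944,0.1514,0.1529,0.1551,0.1496,0.1704,0.2043,0.2562
150,0.2651,0.1347,0.1353,0.1361,0.1298,0.1378,0.1427,0.1669
200,0.2429,0.1229,0.1233,0.1237,0.1176,0.1223,0.1205,0.1378
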