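# molecule: 1M5NI
# channel: electronic
# threshold_eV: 4.0
# units: 1e-20 m2
# note: electronic excitation from threshold-constrained partition; zeros are closed-or-negligible (blank table cells)
energy_eV,sigma_1e-20_m2
0.1,0
0.2,0
0.3,0
0.4,0
0.5,0
0.7,0
1.0,0
1.5,0
2.0,0
3.0,0
4.0,0.1
5.0,0.257
7.0,1.07
10,10.1
15,13.7
20,15.2
30,13.8
40,11.5
50,9.29
70,11.5
100,4.78
150,3.83
200,3.38
300,2.62
400,2.27
500,2.04
700,1.74
1000,1.43
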