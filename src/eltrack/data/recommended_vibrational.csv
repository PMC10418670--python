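# molecule: 1M5NI
# channel: vibrational
# threshold_eV: 0.7
# units: 1e-20 m2
# note: vibrational excitation from threshold-constrained partition; zeros are closed-or-negligible (blank table cells)
energy_eV,sigma_1e-20_m2
0.1,0
0.2,0
0.3,0
0.4,0
0.5,0
0.7,0.1
1.0,3.28
1.5,11.9
2.0,20.3
3.0,20.0
4.0,17.3
5.0,13.9
7.0,14.2
10,0
15,0
20,0
30,0
40,0
50,0
70,0
100,0
150,0
200,0
300,0
400,0
500,0
700,0
1000,0
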