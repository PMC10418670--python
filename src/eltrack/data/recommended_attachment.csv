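# molecule: 1M5NI
# channel: attachment
# threshold_eV: 1.5
# units: 1e-20 m2
# note: electron attachment from resonance extraction; zeros are closed-or-negligible (blank table cells)
energy_eV,sigma_1e-20_m2
0.1,0
0.2,0
0.3,0
0.4,0
0.5,0
0.7,0
1.0,0
1.5,2.39
2.0,14.5
3.0,4.12
4.0,0.425
5.0,1.74
7.0,0.136
10,0.1
15,0.1
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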