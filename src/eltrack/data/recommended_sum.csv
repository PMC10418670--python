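# molecule: 1M5NI
# channel: tcs_reference
# threshold_eV: 0
# units: 1e-20 m2
# note: printed SUM column of the recommended set (reference total for closure checks)
energy_eV,sigma_1e-20_m2
0.1,390
0.2,214
0.3,162
0.4,138
0.5,122
0.7,104
1.0,90.1
1.5,86.5
2.0,98.2
3.0,79.1
4.0,70.7
5.0,68.5
7.0,69.8
10,76.0
15,74.5
20,73.2
30,70.1
40,66.4
50,61.6
70,66.4
100,47.8
150,40.7
200,35.9
300,29.2
400,24.89
500,21.8
700,17.7
1000,13.8
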