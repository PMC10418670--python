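# molecule: 1M5NI
# channel: elastic
# threshold_eV: 0
# units: 1e-20 m2
# note: recommended integral elastic cross-section (SMC below 15 eV, IAM-SCARI above)
energy_eV,sigma_1e-20_m2
0.1,390
0.2,214
0.3,162
0.4,138
0.5,122
0.7,104
1.0,86.8
1.5,72.2
2.0,63.3
3.0,55.0
4.0,52.9
5.0,52.5
7.0,54.4
10,65.8
15,60.5
20,54.9
30,46.8
40,42.3
50,38.6
70,33.6
100,29.1
150,24.3
200,21.2
300,17.1
400,14.6
500,12.7
700,10.2
1000,7.95
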