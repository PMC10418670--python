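# molecule: 1M5NI
# channel: ionization
# threshold_eV: 15
# units: 1e-20 m2
# note: IAM-SCARI total ionization; zeros are closed-or-negligible (blank table cells); opening set at first tabulated entry
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
4.0,0
5.0,0
7.0,0
10,0
15,0.328
20,3.11
30,9.52
40,12.6
50,13.7
70,12.5
100,13.9
150,12.6
200,11.3
300,9.41
400,8.04
500,7.06
700,5.68
1000,4.42
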