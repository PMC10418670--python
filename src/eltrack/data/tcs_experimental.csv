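# molecule: 1M5NI
# channel: tcs_experimental
# threshold_eV: 0
# units: 1e-20 m2
# note: magnetically-confined transmission TCS, uncorrected for forward missing angles
energy_eV,sigma_1e-20_m2
1,84.4
1.2,81.8
1.4,78
1.5,80.4
1.6,86.3
1.8,90.2
2,92.6
2.1,89.2
2.2,86.8
2.3,82.3
2.4,78.8
2.6,74.7
2.8,74
2.9,75.7
3,76.7
3.2,76.1
3.4,75.5
3.6,72.8
3.8,68.5
4,68.1
4.1,66
4.2,63.2
4.4,65
4.6,65.9
4.8,65.9
5,65.3
5.2,64.6
5.4,63.5
5.6,62.4
5.8,64.5
6,66.9
6.2,70.4
6.4,67.6
6.6,64.4
6.8,68.6
7,68.3
7.2,65.1
7.4,66.8
7.6,68.4
7.8,67.8
8,69.7
8.2,67.6
8.4,66.4
8.6,62.9
8.8,64.8
9,65.7
9.2,67.3
9.5,64.7
9.8,67.2
10,73.2
10.5,71.4
11,74.2
12,71.8
13,72
14,71.6
16,71.5
18,70.5
20,70.7
22,69.1
25,69
30,67.9
35,66.4
40,64.3
45,62.7
50,59.7
55,57.9
60,56.3
65,53.9
70,52.1
80,49.6
90,47.9
100,46.2
120,42.6
150,39.3
200,34.8
250,31.3
300,27.6
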