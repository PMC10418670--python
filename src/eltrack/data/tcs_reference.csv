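# molecule: 1M5NI
# channel: tcs_reference
# threshold_eV: 0
# units: 1e-20 m2
# note: TCS + MA, transmission TCS corrected for elastic flux in the forward acceptance cone
energy_eV,sigma_1e-20_m2
1,90.13
1.2,87.77
1.4,84.10
1.5,86.52
1.6,92.40
1.8,96.13
2,98.16
2.1,94.49
2.2,91.77
2.3,86.93
2.4,83.06
2.6,78.23
2.8,76.85
2.9,78.27
3,79.06
3.2,78.20
3.4,77.57
3.6,74.97
3.8,70.88
4,70.72
4.1,68.72
4.2,66.02
4.4,67.98
4.6,69.00
4.8,69.06
5,68.46
5.2,67.68
5.4,66.46
5.6,65.17
5.8,67.07
6,69.24
6.2,72.51
6.4,69.51
6.6,66.12
6.8,70.18
7,69.80
7.2,66.57
7.4,68.31
7.6,69.98
7.8,69.47
8,71.47
8.2,69.46
8.4,68.34
8.6,64.93
8.8,66.92
9,67.93
9.2,69.66
9.5,67.26
9.8,69.93
10,75.99
10.5,74.13
11,76.86
12,74.77
13,74.90
14,74.84
16,74.12
18,73.05
20,73.18
22,71.52
25,71.34
30,70.13
35,68.55
40,66.37
45,64.71
50,61.65
55,59.80
60,58.16
65,55.72
70,53.88
80,51.32
90,49.56
100,47.81
120,44.13
150,40.74
200,36.12
250,32.54
300,28.78
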