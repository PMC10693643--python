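position	rate_cm_per_mb	cm
0	0.5000	0.000000
500000	1.2000	0.250000
1000000	0.3000	0.850000
1500000	2.5000	1.000000
2000000	1.0000	2.250000
2500000	3.2000	2.750000
3000000	0.8000	4.350000
3500000	1.5000	4.750000
4000000	0.4000	5.500000
4500000	2.0000	5.700000
5000000	1.1000	6.700000
5500000	0.6000	7.250000
6000000	2.8000	7.550000
6500000	1.3000	8.950000
7000000	0.9000	9.600000
7500000	1.8000	10.050000
8000000	0.5000	10.950000
8500000	2.2000	11.200000
9000000	1.0000	12.300000
9500000	0.7000	12.800000
10000000	0.7000	13.150000
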