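time_s	r_xm	r_ym	r_xd	r_yd	l	w
0.0	1.3	1.0	0.55	0.48	0.5	0.3
50.0	1.2625	0.97	0.6625000000000001	0.5599999999999999	1.075	0.285
100.0	1.225	0.94	0.775	0.64	1.65	0.27
150.0	1.1875	0.91	0.8875000000000001	0.72	2.2249999999999996	0.255
200.0	1.1500000000000001	0.88	1.0	0.8	2.8	0.24
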