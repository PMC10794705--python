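metric	community_id	n	pipeline_id	mean	sd
AD	BMock12	1	bioBakery3	22.15
AD	BMock12	1	bioBakery4	16.83
AD	BMock12	1	JAMS	33.72
AD	BMock12	1	WGSA2	44.16
AD	BMock12	1	Woltka	42.14
AD	CAMISIM-S1	1	bioBakery3	8.62
AD	CAMISIM-S1	1	bioBakery4	12.76
AD	CAMISIM-S1	1	JAMS	15.04
AD	CAMISIM-S1	1	WGSA2	13.48
AD	CAMISIM-S1	1	Woltka	30.76
AD	CAMISIM-S2	1	bioBakery3	1.23
AD	CAMISIM-S2	1	bioBakery4	7.11
AD	CAMISIM-S2	1	JAMS	4.85
AD	CAMISIM-S2	1	WGSA2	6.38
AD	CAMISIM-S2	1	Woltka	25.88
AD	NIST-EG	1	bioBakery3	10.18
AD	NIST-EG	1	bioBakery4	8.94
AD	NIST-EG	1	JAMS	12.25
AD	NIST-EG	1	WGSA2	10.66
AD	NIST-EG	1	Woltka	22.60
AD	NIST-MIX-A	1	bioBakery3	9.59
AD	NIST-MIX-A	1	bioBakery4	2.84
AD	NIST-MIX-A	1	JAMS	12.35
AD	NIST-MIX-A	1	WGSA2	7.00
AD	NIST-MIX-A	1	Woltka	19.24
AD	NIST-MIX-B	1	bioBakery3	13.65
AD	NIST-MIX-B	1	bioBakery4	9.81
AD	NIST-MIX-B	1	JAMS	13.55
AD	NIST-MIX-B	1	WGSA2	13.08
AD	NIST-MIX-B	1	Woltka	22.88
AD	NIST-MIX-C	1	bioBakery3	14.11
AD	NIST-MIX-C	1	bioBakery4	11.57
AD	NIST-MIX-C	1	JAMS	17.16
AD	NIST-MIX-C	1	WGSA2	14.70
AD	NIST-MIX-C	1	Woltka	24.10
AD	NIST-MIX-D	1	bioBakery3	4.13
AD	NIST-MIX-D	1	bioBakery4	4.11
AD	NIST-MIX-D	1	JAMS	11.22
AD	NIST-MIX-D	1	WGSA2	8.93
AD	NIST-MIX-D	1	Woltka	21.12
AD	Amos-HiLo	5	bioBakery3	8.40	1.07
AD	Amos-HiLo	5	bioBakery4	2.71	0.04
AD	Amos-HiLo	5	JAMS	12.80	0.34
AD	Amos-HiLo	5	WGSA2	12.44	0.29
AD	Amos-HiLo	5	Woltka	16.38	0.11
AD	Amos-Mixed	5	bioBakery3	8.77	0.77
AD	Amos-Mixed	5	bioBakery4	2.00	0.06
AD	Amos-Mixed	5	JAMS	10.42	0.36
AD	Amos-Mixed	5	WGSA2	14.82	0.05
AD	Amos-Mixed	5	Woltka	20.63	0.22
AD	Tourlousse	6	bioBakery3	14.57	0.73
AD	Tourlousse	6	bioBakery4	3.81	0.02
AD	Tourlousse	6	JAMS	8.16	0.40
AD	Tourlousse	6	WGSA2	14.38	0.10
AD	Tourlousse	6	Woltka	23.90	0.26
Sensitivity	BMock12	1	bioBakery3	33.33
Sensitivity	BMock12	1	bioBakery4	58.33
Sensitivity	BMock12	1	JAMS	50.00
Sensitivity	BMock12	1	WGSA2	50.00
Sensitivity	BMock12	1	Woltka	8.33
Sensitivity	CAMISIM-S1	1	bioBakery3	100.00
Sensitivity	CAMISIM-S1	1	bioBakery4	89.47
Sensitivity	CAMISIM-S1	1	JAMS	97.37
Sensitivity	CAMISIM-S1	1	WGSA2	97.37
Sensitivity	CAMISIM-S1	1	Woltka	86.84
Sensitivity	CAMISIM-S2	1	bioBakery3	100.00
Sensitivity	CAMISIM-S2	1	bioBakery4	95.24
Sensitivity	CAMISIM-S2	1	JAMS	100.00
Sensitivity	CAMISIM-S2	1	WGSA2	100.00
Sensitivity	CAMISIM-S2	1	Woltka	80.95
Sensitivity	NIST-EG	1	bioBakery3	85.71
Sensitivity	NIST-EG	1	bioBakery4	92.86
Sensitivity	NIST-EG	1	JAMS	92.86
Sensitivity	NIST-EG	1	WGSA2	100.00
Sensitivity	NIST-EG	1	Woltka	85.71
Sensitivity	NIST-MIX-A	1	bioBakery3	81.82
Sensitivity	NIST-MIX-A	1	bioBakery4	90.91
Sensitivity	NIST-MIX-A	1	JAMS	72.73
Sensitivity	NIST-MIX-A	1	WGSA2	100.00
Sensitivity	NIST-MIX-A	1	Woltka	90.91
Sensitivity	NIST-MIX-B	1	bioBakery3	72.73
Sensitivity	NIST-MIX-B	1	bioBakery4	72.73
Sensitivity	NIST-MIX-B	1	JAMS	81.82
Sensitivity	NIST-MIX-B	1	WGSA2	100.00
Sensitivity	NIST-MIX-B	1	Woltka	90.91
Sensitivity	NIST-MIX-C	1	bioBakery3	63.64
Sensitivity	NIST-MIX-C	1	bioBakery4	63.64
Sensitivity	NIST-MIX-C	1	JAMS	90.91
Sensitivity	NIST-MIX-C	1	WGSA2	100.00
Sensitivity	NIST-MIX-C	1	Woltka	81.82
Sensitivity	NIST-MIX-D	1	bioBakery3	72.73
Sensitivity	NIST-MIX-D	1	bioBakery4	72.73
Sensitivity	NIST-MIX-D	1	JAMS	81.82
Sensitivity	NIST-MIX-D	1	WGSA2	100.00
Sensitivity	NIST-MIX-D	1	Woltka	81.82
Sensitivity	Amos-HiLo	5	bioBakery3	89.47	0.00
Sensitivity	Amos-HiLo	5	bioBakery4	100.00	0.00
Sensitivity	Amos-HiLo	5	JAMS	98.95	2.35
Sensitivity	Amos-HiLo	5	WGSA2	89.47	0.00
Sensitivity	Amos-HiLo	5	Woltka	94.74	0.00
Sensitivity	Amos-Mixed	5	bioBakery3	94.74	0.00
Sensitivity	Amos-Mixed	5	bioBakery4	100.00	0.00
Sensitivity	Amos-Mixed	5	JAMS	100.00	0.00
Sensitivity	Amos-Mixed	5	WGSA2	89.47	0.00
Sensitivity	Amos-Mixed	5	Woltka	94.74	0.00
Sensitivity	Tourlousse	6	bioBakery3	78.95	0.00
Sensitivity	Tourlousse	6	bioBakery4	94.74	0.00
Sensitivity	Tourlousse	6	JAMS	100.00	0.00
Sensitivity	Tourlousse	6	WGSA2	89.47	0.00
Sensitivity	Tourlousse	6	Woltka	94.74	0.00
FPRA	BMock12	1	bioBakery3	2.63
FPRA	BMock12	1	bioBakery4	17.93
FPRA	BMock12	1	JAMS	50.04
FPRA	BMock12	1	WGSA2	37.34
FPRA	BMock12	1	Woltka	11.96
FPRA	CAMISIM-S1	1	bioBakery3	0.53
FPRA	CAMISIM-S1	1	bioBakery4	3.06
FPRA	CAMISIM-S1	1	JAMS	1.44
FPRA	CAMISIM-S1	1	WGSA2	2.04
FPRA	CAMISIM-S1	1	Woltka	8.51
FPRA	CAMISIM-S2	1	bioBakery3	0.06
FPRA	CAMISIM-S2	1	bioBakery4	3.83
FPRA	CAMISIM-S2	1	JAMS	0.21
FPRA	CAMISIM-S2	1	WGSA2	3.91
FPRA	CAMISIM-S2	1	Woltka	30.67
FPRA	NIST-EG	1	bioBakery3	2.66
FPRA	NIST-EG	1	bioBakery4	0.00
FPRA	NIST-EG	1	JAMS	0.21
FPRA	NIST-EG	1	WGSA2	1.16
FPRA	NIST-EG	1	Woltka	26.48
FPRA	NIST-MIX-A	1	bioBakery3	0.85
FPRA	NIST-MIX-A	1	bioBakery4	0.00
FPRA	NIST-MIX-A	1	JAMS	0.05
FPRA	NIST-MIX-A	1	WGSA2	0.68
FPRA	NIST-MIX-A	1	Woltka	30.92
FPRA	NIST-MIX-B	1	bioBakery3	11.42
FPRA	NIST-MIX-B	1	bioBakery4	0.01
FPRA	NIST-MIX-B	1	JAMS	0.27
FPRA	NIST-MIX-B	1	WGSA2	1.09
FPRA	NIST-MIX-B	1	Woltka	31.06
FPRA	NIST-MIX-C	1	bioBakery3	32.06
FPRA	NIST-MIX-C	1	bioBakery4	32.31
FPRA	NIST-MIX-C	1	JAMS	22.33
FPRA	NIST-MIX-C	1	WGSA2	9.16
FPRA	NIST-MIX-C	1	Woltka	69.17
FPRA	NIST-MIX-D	1	bioBakery3	0.06
FPRA	NIST-MIX-D	1	bioBakery4	0.10
FPRA	NIST-MIX-D	1	JAMS	0.02
FPRA	NIST-MIX-D	1	WGSA2	0.25
FPRA	NIST-MIX-D	1	Woltka	13.19
FPRA	Amos-HiLo	5	bioBakery3	0.01	0.02
FPRA	Amos-HiLo	5	bioBakery4	0.00	0.00
FPRA	Amos-HiLo	5	JAMS	0.19	0.07
FPRA	Amos-HiLo	5	WGSA2	0.73	0.08
FPRA	Amos-HiLo	5	Woltka	22.24	0.21
FPRA	Amos-Mixed	5	bioBakery3	3.86	0.22
FPRA	Amos-Mixed	5	bioBakery4	0.00	0.00
FPRA	Amos-Mixed	5	JAMS	2.13	0.12
FPRA	Amos-Mixed	5	WGSA2	4.47	0.10
FPRA	Amos-Mixed	5	Woltka	27.39	0.31
FPRA	Tourlousse	6	bioBakery3	12.23	0.14
FPRA	Tourlousse	6	bioBakery4	4.72	0.04
FPRA	Tourlousse	6	JAMS	6.56	0.32
FPRA	Tourlousse	6	WGSA2	7.82	0.05
FPRA	Tourlousse	6	Woltka	26.14	0.25
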