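gene_no	gene_symbol	probe_id	score
1	ADIPOQ	207175_at	10.7946
2	AMY1A /// AMY1B /// AMY1C /// AMY2A /// AMY2B	208498_s_at	5.5792
3	BMP10	208292_at	-9.7136
4	C2 /// CFB	202357_s_at	7.3188
5	C3	217767_at	7.5830
6	CEBPA	204039_at	5.6280
7	COL21A1	208096_s_at	7.4379
8	DICER1	213229_at	-5.0451
9	DIRAS3	215506_s_at	7.1738
10	EFEMP1	201843_s_at	5.7128
11	FABP4	203980_at	11.0171
12	FHL2	202949_s_at	5.2915
13	GOLGA8A	208798_x_at	6.2200
14	HBA1 /// HBA2	204018_x_at	5.1573
14	HBA1 /// HBA2	217414_x_at	5.2591
14	HBA1 /// HBA2	211745_x_at	5.7071
14	HBA1 /// HBA2	214414_x_at	5.7851
14	HBA1 /// HBA2	209458_x_at	5.2950
14	HBA1 /// HBA2	211699_x_at	5.3233
15	HBB	209116_x_at	5.4556
16	HP /// HPR	208470_s_at	8.6784
16	HP /// HPR	206697_s_at	7.9905
17	IGF1	209541_at	6.1854
18	IGFBP2	202718_at	5.4903
19	IGH@ /// IGHA1 /// IGHA2 /// IGHV3OR16-13 /// LOC100126583	217022_s_at	6.4910
20	IGH@ /// IGHG1 /// IGHG2 /// IGHM /// IGHV4-31	211430_s_at	6.2667
21	IGL@	214677_x_at	6.3976
21	IGL@	209138_x_at	6.2909
22	JUP /// KRT19	201650_at	7.8226
23	LAMB1	211651_s_at	5.0672
23	LAMB1	201505_at	6.4921
24	LBH	221011_s_at	5.5211
25	LOC100133662 /// RPS4Y1	201909_at	-6.9535
26	LPL	203549_s_at	6.3296
26	LPL	203548_s_at	6.1435
27	MEST	202016_at	5.5929
28	MMD	203414_at	5.4544
29	MSLN	204885_s_at	5.5812
30	MXRA5	209596_at	5.3933
31	MYL2	209742_s_at	5.8398
32	NPR3	219789_at	-5.9588
33	PCK1	208383_s_at	5.7877
34	PFKFB3	202464_s_at	6.0757
35	PLA2G2A	203649_s_at	6.9397
36	PLIN	205913_at	10.0271
37	POMZP3 /// ZP3	204148_s_at	5.0854
38	PRG4	206007_at	6.4669
39	PRKACA	216234_s_at	-5.7289
40	PSD3	203354_s_at	-5.4524
41	RBP4	219140_s_at	10.2064
42	RGS1	216834_at	8.3498
43	SFRP1	202037_s_at	7.4615
44	SGK1	201739_at	6.3130
45	SLC16A7	207057_at	-5.0912
46	SLPI	203021_at	9.6451
47	SPP1	209875_s_at	9.1800
48	SULF1	212353_at	6.0712
48	SULF1	212354_at	5.7653
49	TF	203400_s_at	10.0283
49	TF	214063_s_at	6.0445
50	UPK3B	206658_at	6.7799
51	XIST	221728_x_at	8.1499
51	XIST	214218_s_at	6.1087
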