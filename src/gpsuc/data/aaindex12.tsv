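# Twelve amino-acid property scales (AAindex accessions), values per
# canonical residue. NA entries in the source scales are stored as 0.
accession	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
TSAJ990101	89.3	102.5	114.4	138.8	190.8	63.8	157.5	163.0	165.1	163.1	165.8	122.4	121.6	146.9	190.3	94.2	119.6	138.2	226.4	194.6
MAXF760101	1.43	0.94	0.92	1.67	1.19	0.46	0.98	1.04	1.27	1.36	1.53	0.64	0.49	1.22	1.18	0.70	0.78	0.98	1.01	0.69
NAKH920108	9.36	2.56	0.94	0.94	10.99	6.17	0.47	13.73	0.58	16.64	3.93	2.31	1.96	1.14	0.27	5.58	4.68	12.43	2.20	3.13
BLAM930101	0.96	0.42	0.42	0.53	0.59	0.00	0.57	0.84	0.73	0.92	0.86	0.39	-2.50	0.80	0.77	0.53	0.54	0.63	0.58	0.72
BIOV880101	16.0	168.0	-78.0	-106.0	189.0	-13.0	50.0	151.0	-141.0	145.0	124.0	-74.0	-20.0	-73.0	-70.0	-70.0	-38.0	123.0	145.0	53.0
CEDJ970104	7.9	1.9	5.5	7.1	3.9	7.1	2.1	5.2	6.7	8.6	2.4	4.0	5.3	4.4	4.9	6.6	5.3	6.8	1.2	3.1
NOZY710101	0.5	0	0	0	2.5	0	0.5	1.8	0	1.8	1.3	0	0	0	0	0	0.4	1.5	3.4	2.3
KLEP840101	0	0	-1	-1	0	0	0	0	1	0	0	0	0	0	1	0	0	0	0	0
NAKH900109	8.63	1.53	3.26	3.36	6.77	8.00	1.81	8.67	3.30	12.26	3.00	3.27	3.88	2.86	3.86	6.79	5.39	8.06	2.17	3.13
LIFS790101	0.92	1.16	0.48	0.61	1.25	0.61	0.93	1.81	0.70	1.30	1.19	0.60	0.40	0.95	0.93	0.82	1.12	1.81	1.54	1.53
HUTJ700103	154.33	219.79	194.91	223.16	204.74	127.90	242.54	233.21	300.46	232.30	202.65	207.90	179.93	235.51	341.01	174.06	205.80	207.60	237.01	229.15
MIYS990104	-0.04	-0.38	0.19	0.23	-0.38	0.09	-0.04	-0.34	0.33	-0.37	-0.30	0.13	0.19	0.14	0.07	0.12	0.03	-0.29	-0.33	-0.29
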