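pt	soc	ror	ror_low	ror_high	prr	prr_low	prr_high	chi2	p	ic	ic025	ebgm	ebgm05	a	b	c	d
Gastrooesophageal reflux disease	Gastrointestinal disorders	40.29	34.22	47.43	2.97	2.52	3.49	5511.58	0.00E+00	4.82	4.3	28.3	24.04	207	19836	488	1883950
Dyspepsia	Gastrointestinal disorders	36.91	32.9	41.4	4.28	3.82	4.79	10109.85	0.00E+00	4.72	4.35	26.4	23.54	409	19634	1063	1883375
Incorrect dose administered	Injury, poisoning and procedural complications	40.4	39.06	41.8	29.1	28.35	29.87	120715.28	0.00E+00	4.49	4.38	22.46	21.71	5752	14291	18587	1865851
Vomiting	Gastrointestinal disorders	27.56	25.63	29.64	2.67	2.49	2.87	18475.33	0.00E+00	4.38	4.14	20.75	19.3	970	19073	3471	1880967
Blood glucose abnormal	Investigations	20.07	17.1	23.55	4.27	3.65	5.01	2711.41	0.00E+00	4.05	3.53	16.59	14.14	183	19860	865	1883573
Injection site haemorrhage	General disorders and administration site conditions	18.36	17.26	19.53	17.27	16.29	18.32	16337.90	0.00E+00	3.88	3.68	14.75	13.86	1256	18787	6836	1877602
Increased appetite	Metabolism and nutrition disorders	18.85	16.2	21.94	10.28	8.84	11.94	2820.00	0.00E+00	3.98	3.48	15.75	13.53	202	19841	1017	1883421
Inappropriate schedule of product administration	Injury, poisoning and procedural complications	11.51	10.71	12.36	2.61	2.44	2.8	7180.48	0.00E+00	3.32	3.08	9.99	9.3	874	19169	7436	1877002
Injection site pain	General disorders and administration site conditions	12.02	11.52	12.54	10.51	10.13	10.91	21533.37	0.00E+00	3.26	3.12	9.55	9.16	2742	17301	24527	1859911
Thyroid hormones increased	Investigations	13.63	9.97	18.64	4.21	3.08	5.75	459.16	7.34E-102	3.59	2.57	12.01	8.78	45	19998	311	1884127
Eructation	Gastrointestinal disorders	10.43	9.49	11.47	36.17	32.99	39.67	3671.53	0.00E+00	3.22	2.9	9.3	8.46	489	19554	4506	1879932
Glycosylated haemoglobin abnormal	Investigations	11.48	9.07	14.53	5.72	4.53	7.24	662.82	3.63E-146	3.37	2.59	10.31	8.15	78	19965	641	1883797
Accidental underdose	Injury, poisoning and procedural complications	10.22	9.03	11.57	18.68	16.52	21.11	2073.93	0.00E+00	3.2	2.79	9.21	8.13	280	19763	2609	1881829
Pancreatitis	Gastrointestinal disorders	10.09	8.79	11.58	5.87	5.12	6.73	1661.59	0.00E+00	3.19	2.73	9.12	7.95	227	19816	2137	1882301
Injection site paraesthesia	General disorders and administration site conditions	10.34	8.71	12.28	23.5	19.82	27.87	1102.75	8.36E-242	3.23	2.66	9.36	7.89	146	19897	1336	1883102
Blood glucose increased	Investigations	9.49	8.7	10.36	3.94	3.62	4.29	3805.79	0.00E+00	3.09	2.8	8.51	7.8	566	19477	5751	1878687
Injection site injury	General disorders and administration site conditions	8.03	7.11	9.06	39.88	35.39	44.94	1611.39	0.00E+00	2.89	2.48	7.39	6.55	288	19755	3415	1881023
Diabetic retinopathy	Eye disorders	9.04	7.05	11.6	4.63	3.61	5.94	442.48	3.12E-98	3.06	2.24	8.32	6.48	68	19975	709	1883729
Hunger	General disorders and administration site conditions	7.92	6.9	9.1	19.89	17.34	22.82	1209.40	5.52E-265	2.87	2.41	7.32	6.37	219	19824	2624	1881814
Product administered at inappropriate site	Injury, poisoning and procedural complications	7.78	6.8	8.91	6.59	5.77	7.53	1247.62	2.74E-273	2.85	2.4	7.2	6.29	231	19812	2819	1881619
Product prescribing error	Injury, poisoning and procedural complications	6.64	5.73	7.7	2.6	2.24	3.01	847.25	2.88E-186	2.64	2.15	6.22	5.37	191	19852	2726	1881712
Counterfeit product administered	Injury, poisoning and procedural complications	7.02	5.51	8.94	7.66	6.02	9.75	339.86	6.86E-76	2.72	1.93	6.58	5.17	71	19972	954	1883484
Impaired gastric emptying	Gastrointestinal disorders	5.92	5.1	6.86	11.44	9.88	13.25	716.22	8.90E-158	2.48	1.99	5.58	4.82	188	19855	3011	1881427
Wrong patient received product	Injury, poisoning and procedural complications	5.94	4.98	7.08	5.96	5.01	7.09	514.49	6.68E-114	2.49	1.91	5.62	4.71	134	19909	2133	1882305
Starvation	Metabolism and nutrition disorders	5.18	4.25	6.3	37.28	30.65	45.36	333.73	1.48E-74	2.3	1.65	4.94	4.06	105	19938	1915	1882523
Abdominal rigidity	Gastrointestinal disorders	5.56	4.23	7.29	4.01	3.06	5.27	193.46	5.59E-44	2.4	1.51	5.29	4.03	55	19988	933	1883505
Feeding disorder	Metabolism and nutrition disorders	4.75	4.11	5.48	5.16	4.47	5.95	546.52	7.18E-121	2.18	1.7	4.53	3.92	196	19847	3913	1880525
Injection site urticaria	General disorders and administration site conditions	4.33	3.87	4.85	9.99	8.94	11.15	784.33	1.38E-172	2.05	1.67	4.14	3.7	325	19718	7140	1877298
Nausea	Gastrointestinal disorders	4.29	4.11	4.48	3.89	3.75	4.04	5233.22	0.00E+00	1.92	1.77	3.78	3.62	2456	17587	59363	1825075
Abdominal distension	Gastrointestinal disorders	4.22	3.73	4.77	2.45	2.17	2.76	631.49	2.37E-139	2.02	1.61	4.04	3.58	272	19771	6122	1878316
Abdominal pain upper	Gastrointestinal disorders	4.01	3.66	4.4	2.32	2.12	2.54	1030.04	5.31E-226	1.93	1.63	3.82	3.49	486	19557	11596	1872842
Injection site bruising	General disorders and administration site conditions	3.72	3.44	4.03	9.25	8.57	9.99	1216.23	1.81E-266	1.82	1.56	3.54	3.27	655	19388	16938	1867500
Thyroid mass	Endocrine disorders	4.28	3.37	5.46	2.83	2.22	3.6	165.64	6.63E-38	2.05	1.25	4.13	3.24	69	19974	1518	1882920
Blood glucose fluctuation	Investigations	4.01	3.32	4.84	3.44	2.86	4.16	243.20	7.91E-55	1.95	1.33	3.87	3.2	113	19930	2663	1881775
Weight decreased	Investigations	3.52	3.26	3.81	2.23	2.07	2.41	1159.35	4.16E-254	1.74	1.48	3.35	3.1	689	19354	18858	1865580
Injection site discolouration	General disorders and administration site conditions	3.17	2.7	3.73	3.65	3.1	4.29	215.74	7.68E-49	1.63	1.09	3.09	2.62	151	19892	4498	1879940
Food craving	Metabolism and nutrition disorders	2.98	2.54	3.5	13.6	11.61	15.94	197.61	6.94E-45	1.54	1.01	2.91	2.48	156	19887	4945	1879493
Medullary thyroid cancer	Neoplasms benign, malignant and unspecified (incl cysts and polyps)	3.53	2.54	4.9	9.1	6.56	12.63	64.41	1.01E-15	1.78	0.72	3.43	2.47	37	20006	988	1883450
Injection site erythema	General disorders and administration site conditions	2.76	2.58	2.95	11.05	10.37	11.78	963.55	1.51E-211	1.39	1.17	2.63	2.46	928	19115	32614	1851824
Decreased appetite	Metabolism and nutrition disorders	2.68	2.5	2.88	3.44	3.21	3.67	833.70	2.55E-183	1.36	1.13	2.57	2.4	847	19196	30486	1853952
Off label use	Injury, poisoning and procedural complications	2.77	2.66	2.88	2.5	2.41	2.58	2887.96	0.00E+00	1.3	1.17	2.46	2.36	3101	16942	116856	1767582
Appetite disorder	Metabolism and nutrition disorders	2.6	2.14	3.17	3.44	2.83	4.18	99.60	1.87E-23	1.35	0.71	2.55	2.1	104	19939	3765	1880673
Hypoglycaemia	Metabolism and nutrition disorders	2.46	2.14	2.84	3.99	3.47	4.59	167.16	3.08E-38	1.27	0.8	2.41	2.1	199	19844	7636	1876802
Injection site rash	General disorders and administration site conditions	2.34	2.11	2.6	10.09	9.12	11.16	278.21	1.84E-62	1.19	0.85	2.29	2.06	377	19666	15287	1869151
Injection site discomfort	General disorders and administration site conditions	2.42	2.09	2.8	7	6.05	8.09	150.06	1.68E-34	1.25	0.76	2.37	2.05	186	19857	7259	1877179
Injection site pruritus	General disorders and administration site conditions	2.27	2.09	2.47	10.2	9.41	11.07	389.92	8.62E-87	1.14	0.86	2.21	2.03	578	19465	24326	1860112
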