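soc	soc_code	ror	ror_low	ror_high	prr	prr_low	prr_high	chi2	p	ic	ic025	ebgm	ebgm05	a	b	c	d
Injury, poisoning and procedural complications	10022117	12.69	12.34	13.05	6.49	6.4	6.58	50542.75	0.00E+00	2.62	2.54	6.13	5.96	10634	9409	154120	1730318
General disorders and administration site conditions	10018065	7.62	7.41	7.85	5.03	4.94	5.12	26175.61	0.00E+00	2.27	2.18	4.82	4.69	7851	12192	146800	1737638
Gastrointestinal disorders	10017947	7.79	7.55	8.04	5.84	5.71	5.98	22943.94	0.00E+00	2.47	2.37	5.56	5.39	5759	14284	92690	1791748
Metabolism and nutrition disorders	10027433	3.38	3.22	3.55	3.17	3.03	3.31	2675.34	0.00E+00	1.63	1.47	3.1	2.95	1809	18234	53677	1830761
Investigations	10022891	5.81	5.52	6.12	5.41	5.16	5.67	5784.67	0.00E+00	2.37	2.2	5.17	4.91	1674	18369	29089	1855349
Endocrine disorders	10014698	4.28	3.37	5.46	4.27	3.36	5.44	165.64	6.63E-38	2.05	1.25	4.13	3.24	69	19974	1518	1882920
Eye disorders	10015919	9.04	7.05	11.6	9.02	7.03	11.56	442.48	3.12E-98	3.06	2.24	8.32	6.48	68	19975	709	1883729
Neoplasms benign, malignant and unspecified (incl cysts and polyps)	10029104	3.53	2.54	4.9	3.52	2.54	4.89	64.41	1.01E-15	1.78	0.72	3.43	2.47	37	20006	988	1883450
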