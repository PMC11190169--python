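pt	soc	a	b	c	d
Gastrooesophageal reflux disease	Gastrointestinal disorders	207	19836	488	1883950
Dyspepsia	Gastrointestinal disorders	409	19634	1063	1883375
Incorrect dose administered	Injury, poisoning and procedural complications	5752	14291	18587	1865851
Vomiting	Gastrointestinal disorders	970	19073	3471	1880967
Blood glucose abnormal	Investigations	183	19860	865	1883573
Injection site haemorrhage	General disorders and administration site conditions	1256	18787	6836	1877602
Increased appetite	Metabolism and nutrition disorders	202	19841	1017	1883421
Inappropriate schedule of product administration	Injury, poisoning and procedural complications	874	19169	7436	1877002
Injection site pain	General disorders and administration site conditions	2742	17301	24527	1859911
Thyroid hormones increased	Investigations	45	19998	311	1884127
Eructation	Gastrointestinal disorders	489	19554	4506	1879932
Glycosylated haemoglobin abnormal	Investigations	78	19965	641	1883797
Accidental underdose	Injury, poisoning and procedural complications	280	19763	2609	1881829
Pancreatitis	Gastrointestinal disorders	227	19816	2137	1882301
Injection site paraesthesia	General disorders and administration site conditions	146	19897	1336	1883102
Blood glucose increased	Investigations	566	19477	5751	1878687
Injection site injury	General disorders and administration site conditions	288	19755	3415	1881023
Diabetic retinopathy	Eye disorders	68	19975	709	1883729
Hunger	General disorders and administration site conditions	219	19824	2624	1881814
Product administered at inappropriate site	Injury, poisoning and procedural complications	231	19812	2819	1881619
Product prescribing error	Injury, poisoning and procedural complications	191	19852	2726	1881712
Counterfeit product administered	Injury, poisoning and procedural complications	71	19972	954	1883484
Impaired gastric emptying	Gastrointestinal disorders	188	19855	3011	1881427
Wrong patient received product	Injury, poisoning and procedural complications	134	19909	2133	1882305
Starvation	Metabolism and nutrition disorders	105	19938	1915	1882523
Abdominal rigidity	Gastrointestinal disorders	55	19988	933	1883505
Feeding disorder	Metabolism and nutrition disorders	196	19847	3913	1880525
Injection site urticaria	General disorders and administration site conditions	325	19718	7140	1877298
Nausea	Gastrointestinal disorders	2456	17587	59363	1825075
Abdominal distension	Gastrointestinal disorders	272	19771	6122	1878316
Abdominal pain upper	Gastrointestinal disorders	486	19557	11596	1872842
Injection site bruising	General disorders and administration site conditions	655	19388	16938	1867500
Thyroid mass	Endocrine disorders	69	19974	1518	1882920
Blood glucose fluctuation	Investigations	113	19930	2663	1881775
Weight decreased	Investigations	689	19354	18858	1865580
Injection site discolouration	General disorders and administration site conditions	151	19892	4498	1879940
Food craving	Metabolism and nutrition disorders	156	19887	4945	1879493
Medullary thyroid cancer	Neoplasms benign, malignant and unspecified (incl cysts and polyps)	37	20006	988	1883450
Injection site erythema	General disorders and administration site conditions	928	19115	32614	1851824
Decreased appetite	Metabolism and nutrition disorders	847	19196	30486	1853952
Off label use	Injury, poisoning and procedural complications	3101	16942	116856	1767582
Appetite disorder	Metabolism and nutrition disorders	104	19939	3765	1880673
Hypoglycaemia	Metabolism and nutrition disorders	199	19844	7636	1876802
Injection site rash	General disorders and administration site conditions	377	19666	15287	1869151
Injection site discomfort	General disorders and administration site conditions	186	19857	7259	1877179
Injection site pruritus	General disorders and administration site conditions	578	19465	24326	1860112
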