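pt_code	pt_name	soc_code	soc_name	primary_soc
90000001	Gastrooesophageal reflux disease	10017947	Gastrointestinal disorders	True
90000002	Dyspepsia	10017947	Gastrointestinal disorders	True
90000003	Incorrect dose administered	10022117	Injury, poisoning and procedural complications	True
90000004	Vomiting	10017947	Gastrointestinal disorders	True
90000005	Blood glucose abnormal	10022891	Investigations	True
90000006	Injection site haemorrhage	10018065	General disorders and administration site conditions	True
90000007	Increased appetite	10027433	Metabolism and nutrition disorders	True
90000008	Inappropriate schedule of product administration	10022117	Injury, poisoning and procedural complications	True
90000009	Injection site pain	10018065	General disorders and administration site conditions	True
90000010	Thyroid hormones increased	10022891	Investigations	True
90000011	Eructation	10017947	Gastrointestinal disorders	True
90000012	Glycosylated haemoglobin abnormal	10022891	Investigations	True
90000013	Accidental underdose	10022117	Injury, poisoning and procedural complications	True
90000014	Pancreatitis	10017947	Gastrointestinal disorders	True
90000015	Injection site paraesthesia	10018065	General disorders and administration site conditions	True
90000016	Blood glucose increased	10022891	Investigations	True
90000017	Injection site injury	10018065	General disorders and administration site conditions	True
90000018	Diabetic retinopathy	10015919	Eye disorders	True
90000019	Hunger	10018065	General disorders and administration site conditions	True
90000020	Product administered at inappropriate site	10022117	Injury, poisoning and procedural complications	True
90000021	Product prescribing error	10022117	Injury, poisoning and procedural complications	True
90000022	Counterfeit product administered	10022117	Injury, poisoning and procedural complications	True
90000023	Impaired gastric emptying	10017947	Gastrointestinal disorders	True
90000024	Wrong patient received product	10022117	Injury, poisoning and procedural complications	True
90000025	Starvation	10027433	Metabolism and nutrition disorders	True
90000026	Abdominal rigidity	10017947	Gastrointestinal disorders	True
90000027	Feeding disorder	10027433	Metabolism and nutrition disorders	True
90000028	Injection site urticaria	10018065	General disorders and administration site conditions	True
90000029	Nausea	10017947	Gastrointestinal disorders	True
90000030	Abdominal distension	10017947	Gastrointestinal disorders	True
90000031	Abdominal pain upper	10017947	Gastrointestinal disorders	True
90000032	Injection site bruising	10018065	General disorders and administration site conditions	True
90000033	Thyroid mass	10014698	Endocrine disorders	True
90000034	Blood glucose fluctuation	10022891	Investigations	True
90000035	Weight decreased	10022891	Investigations	True
90000036	Injection site discolouration	10018065	General disorders and administration site conditions	True
90000037	Food craving	10027433	Metabolism and nutrition disorders	True
90000038	Medullary thyroid cancer	10029104	Neoplasms benign, malignant and unspecified (incl cysts and polyps)	True
90000039	Injection site erythema	10018065	General disorders and administration site conditions	True
90000040	Decreased appetite	10027433	Metabolism and nutrition disorders	True
90000041	Off label use	10022117	Injury, poisoning and procedural complications	True
90000042	Appetite disorder	10027433	Metabolism and nutrition disorders	True
90000043	Hypoglycaemia	10027433	Metabolism and nutrition disorders	True
90000044	Injection site rash	10018065	General disorders and administration site conditions	True
90000045	Injection site discomfort	10018065	General disorders and administration site conditions	True
90000046	Injection site pruritus	10018065	General disorders and administration site conditions	True
90000001	Gastrooesophageal reflux disease	10022891	Investigations	False
91000001	Simulated event 001	99000001	Simulated SOC 1	True
91000002	Simulated event 002	99000002	Simulated SOC 2	True
91000003	Simulated event 003	99000003	Simulated SOC 3	True
91000004	Simulated event 004	99000004	Simulated SOC 4	True
91000005	Simulated event 005	99000005	Simulated SOC 5	True
91000006	Simulated event 006	99000006	Simulated SOC 6	True
91000007	Simulated event 007	99000001	Simulated SOC 1	True
91000008	Simulated event 008	99000002	Simulated SOC 2	True
91000009	Simulated event 009	99000003	Simulated SOC 3	True
91000010	Simulated event 010	99000004	Simulated SOC 4	True
91000011	Simulated event 011	99000005	Simulated SOC 5	True
91000012	Simulated event 012	99000006	Simulated SOC 6	True
91000013	Simulated event 013	99000001	Simulated SOC 1	True
91000014	Simulated event 014	99000002	Simulated SOC 2	True
91000015	Simulated event 015	99000003	Simulated SOC 3	True
91000016	Simulated event 016	99000004	Simulated SOC 4	True
91000017	Simulated event 017	99000005	Simulated SOC 5	True
91000018	Simulated event 018	99000006	Simulated SOC 6	True
91000019	Simulated event 019	99000001	Simulated SOC 1	True
91000020	Simulated event 020	99000002	Simulated SOC 2	True
91000021	Simulated event 021	99000003	Simulated SOC 3	True
91000022	Simulated event 022	99000004	Simulated SOC 4	True
91000023	Simulated event 023	99000005	Simulated SOC 5	True
91000024	Simulated event 024	99000006	Simulated SOC 6	True
91000025	Simulated event 025	99000001	Simulated SOC 1	True
91000026	Simulated event 026	99000002	Simulated SOC 2	True
91000027	Simulated event 027	99000003	Simulated SOC 3	True
91000028	Simulated event 028	99000004	Simulated SOC 4	True
91000029	Simulated event 029	99000005	Simulated SOC 5	True
91000030	Simulated event 030	99000006	Simulated SOC 6	True
91000031	Simulated event 031	99000001	Simulated SOC 1	True
91000032	Simulated event 032	99000002	Simulated SOC 2	True
91000033	Simulated event 033	99000003	Simulated SOC 3	True
91000034	Simulated event 034	99000004	Simulated SOC 4	True
91000035	Simulated event 035	99000005	Simulated SOC 5	True
91000036	Simulated event 036	99000006	Simulated SOC 6	True
91000037	Simulated event 037	99000001	Simulated SOC 1	True
91000038	Simulated event 038	99000002	Simulated SOC 2	True
91000039	Simulated event 039	99000003	Simulated SOC 3	True
91000040	Simulated event 040	99000004	Simulated SOC 4	True
91000041	Simulated event 041	99000005	Simulated SOC 5	True
91000042	Simulated event 042	99000006	Simulated SOC 6	True
91000043	Simulated event 043	99000001	Simulated SOC 1	True
91000044	Simulated event 044	99000002	Simulated SOC 2	True
91000045	Simulated event 045	99000003	Simulated SOC 3	True
91000046	Simulated event 046	99000004	Simulated SOC 4	True
91000047	Simulated event 047	99000005	Simulated SOC 5	True
91000048	Simulated event 048	99000006	Simulated SOC 6	True
91000049	Simulated event 049	99000001	Simulated SOC 1	True
91000050	Simulated event 050	99000002	Simulated SOC 2	True
91000051	Simulated event 051	99000003	Simulated SOC 3	True
91000052	Simulated event 052	99000004	Simulated SOC 4	True
91000053	Simulated event 053	99000005	Simulated SOC 5	True
91000054	Simulated event 054	99000006	Simulated SOC 6	True
91000055	Simulated event 055	99000001	Simulated SOC 1	True
91000056	Simulated event 056	99000002	Simulated SOC 2	True
91000057	Simulated event 057	99000003	Simulated SOC 3	True
91000058	Simulated event 058	99000004	Simulated SOC 4	True
91000059	Simulated event 059	99000005	Simulated SOC 5	True
91000060	Simulated event 060	99000006	Simulated SOC 6	True
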