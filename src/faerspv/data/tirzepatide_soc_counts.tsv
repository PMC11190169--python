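soc	soc_code	a	b	c	d
Injury, poisoning and procedural complications	10022117	10634	9409	154120	1730318
General disorders and administration site conditions	10018065	7851	12192	146800	1737638
Gastrointestinal disorders	10017947	5759	14284	92690	1791748
Metabolism and nutrition disorders	10027433	1809	18234	53677	1830761
Investigations	10022891	1674	18369	29089	1855349
Endocrine disorders	10014698	69	19974	1518	1882920
Eye disorders	10015919	68	19975	709	1883729
Neoplasms benign, malignant and unspecified (incl cysts and polyps)	10029104	37	20006	988	1883450
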