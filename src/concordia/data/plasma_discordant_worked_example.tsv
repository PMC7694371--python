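gene_symbol	protein_name	lfc_transcript	rank_transcript	lfc_protein	rank_protein	average_rank
MBP	Myelin basic protein	-1.21	3521	2.05	3234	3377.5
PACS1	Phosphofurin acidic cluster sorting protein 1	-0.51	3218	3.34	3534	3376
APP	Amyloid-beta precursor protein	-0.77	3395	2.26	3318	3356.5
DSP	Desmoplakin	-1.43	3544	1.48	2938	3241
FCGBP	IgGFc-binding protein	-0.46	3156	2.11	3264	3210
LAMP2	Lysosome-associated membrane glycoprotein 2	-0.71	3369	1.64	3043	3206
BOLA2B	BolA-like protein 2	-0.28	2823	3.30	3532	3177.5
PTPRF	Receptor-type tyrosine-protein phosphatase F	-1.03	3487	1.33	2828	3157.5
DCN	Decorin	-0.77	3400	1.39	2875	3137.5
AK3	GTP:AMP phosphotransferase AK3, mitochondrial	-0.51	3219	1.58	3006	3112.5
HTRA1	Serine protease HTRA1	-1.47	3550	1.12	2670	3110
OGN	Mimecan	-0.89	3445	1.19	2731	3088
GOLIM4	Golgi integral membrane protein 4	-0.73	3379	1.25	2771	3075
LAMB2	Laminin subunit beta-2	-0.64	3331	1.29	2799	3065
ITM2B	Integral membrane protein 2B	-0.63	3319	1.24	2766	3042.5
SDHB	Succinate dehydrogenase [ubiquinone] iron-sulfur subunit, mitochondrial	-0.31	2870	1.90	3175	3022.5
CST3	Cystatin-C	-0.38	3034	1.51	2962	2998
LTBP4	Latent-transforming growth factor beta-binding protein 4	-0.53	3239	1.21	2745	2992
PPP3CA	Serine/threonine-protein phosphatase 2B catalytic subunit alpha isoform	-0.54	3245	1.15	2694	2969.5
HEXA	Beta-hexosaminidase subunit alpha	-0.27	2765	1.87	3163	2964
PCSK1N	ProSAAS	-0.83	3426	0.91	2483	2954.5
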