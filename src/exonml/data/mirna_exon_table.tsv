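ensembl_exon_id	mirbase_id	gene_symbol	alc1	alc2	cont1	cont2	bh_p	exon_log2fc	gene_log2fc
ENSGALG00000025382+ENSGALG00000001043:E020	gga-mir-1647	REXO1	611	713	893	949	0.004	0.449	-0.043
ENSGALG00000003532+ENSGALG00000027517:E001	gga-mir-3064	DDX5	3896	3546	6352	6185	1.08E-12	0.337	0.178
ENSGALG00000009621+ENSGALG00000027736:E005	gga-mir-3533	ACTB	1446	1349	2016	1972	0.001	0.018	0.439
ENSGALG00000027916+ENSGALG00000008553:E001	gga-mir-6544	INO80	464	395	495	518	0.065	0.106	-0.194
ENSGALG00000042088+ENSGALG00000028980:E001	gga-mir-6590	ATG2B	77	71	88	66	0.060	0.322	-0.681
ENSGALG00000030446+ENSGALG00000041520:E001	gga-mir-6593	CCDC94	52	58	110	112	0.043	0.470	0.438
ENSGALG00000028549+ENSGALG00000000721:E001	gga-mir-6602	SLC41A1	77	84	100	83	0.002	0.578	-0.655
ENSGALG00000026724+ENSGALG00000041331:E001	gga-mir-6604	RRP12	93	116	252	270	0.0003	0.605	0.248
ENSGALG00000005516+ENSGALG00000028228:E001	gga-mir-6639	HEATR6	479	473	742	717	0.020	0.230	0.186
ENSGALG00000006144+ENSGALG00000026170:E015	gga-mir-6667	CDK10	179	199	341	350	0.044	0.173	0.567
ENSGALG00000025785+ENSGALG00000008380:E001	gga-mir-6706	DGKZ	1190	1350	1598	1662	0.025	0.104	0.087
ENSGALG00000039830+ENSGALG00000034961:E001	gga-mir-6710	DHX30	903	1088	1398	1385	4.65E-06	0.294	-0.0013
ENSGALG00000009476+ENSGALG00000025191:E001	gga-mir-1650	CDK6	1464	1393	1336	1377	0.006	-0.141	-0.204
ENSGALG00000025345+ENSGALG00000028561:E027	gga-mir-1665	SZT2	6	7	2	3	0.093	-1.776	0.282
ENSGALG00000003532+ENSGALG00000027517:E011	gga-mir-3064	DDX5	51	46	48	35	0.041	-0.632	0.178
ENSGALG00000003532+ENSGALG00000027517:E013	gga-mir-3064	DDX5	258	247	230	254	0.0002	-0.479	0.178
ENSGALG00000038017+ENSGALG00000032029:E001	gga-mir-6542	SRF	15	15	5	13	0.090	-1.221	0.241
ENSGALG00000025769+ENSGALG00000015451:E003	gga-mir-6565	ZNF462	1605	1486	776	757	1.90E-38	-0.729	-0.496
ENSGALG00000028549+ENSGALG00000000721:E012	gga-mir-6602	SLC41A1	206	193	129	100	0.0007	-0.413	-0.655
ENSGALG00000026724+ENSGALG00000041331:E028	gga-mir-6604	RRP12	13	11	6	10	0.072	-1.271	0.248
ENSGALG00000026724+ENSGALG00000041331:E027	gga-mir-6604	RRP12	27	41	28	39	0.073	-0.742	0.248
ENSGALG00000030904+ENSGALG00000038881:E064	gga-mir-6619	LRP1	26	19	11	9	0.074	-1.200	-0.024
ENSGALG00000025785+ENSGALG00000008380:E009	gga-mir-6706	DGKZ	8	9	5	1	0.081	-1.686	0.087
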