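dataset	feature_id	control	gut	urt	lrt
Aedes	Enterobacter_1	40.06	25.89	16.73	22.48
Aedes	Enterobacter_2	19.64	13.05	6.27	8.33
Aedes	Serratia_1	5.69	10.16	2.93	3.23
Aedes	Cutibacterium_1	1.11	0	0	0
Aegypti	Serratia_1	6.34	0	NA	NA
Aegypti	Halomonas_1	5.22	0	NA	NA
Aegypti	Halomonas_2	4.54	0	NA	NA
Aegypti	Serratia_2	3.79	0	NA	NA
Aegypti	Serratia_3	2.18	0	NA	NA
Aegypti	Serratia_4	2.16	0	NA	NA
Aegypti	Halomonas_3	2.14	0	NA	NA
Aegypti	Halomonas_4	2.06	0	NA	NA
Aegypti	Halomonas_5	1.78	0	NA	NA
Aegypti	Halomonas_6	1.67	0	NA	NA
Aegypti	Vibrio_1	1.24	0	NA	NA
Aegypti	Marinimicrobium_1	1.16	0	NA	NA
Aegypti	Serratia_5	1.15	0	NA	NA
Aegypti	Serratia_6	1.08	0	NA	NA
Aegypti	Halomonas_7	1.06	0	NA	NA
Aegypti	Halomonas_8	1.06	0	NA	NA
Albopictus	Pseudomonas_1	60.64	2.76	NA	NA
Albopictus	Chryseobacterium_1	4.82	2.66	NA	NA
Albopictus	Janthinobacterium_1	3.24	1.72	NA	NA
Albopictus	Pseudomonas_2	2.89	0.25	NA	NA
Albopictus	Pseudomonas_3	2.07	0.07	NA	NA
Albopictus	Acinetobacter_1	1.53	0.03	NA	NA
Albopictus	Janthinobacterium_2	1.08	0.5	NA	NA
Anopheles1	Aeromonas_1	17.74	9.93	NA	NA
Anopheles1	Pantoea_1	12.38	8.75	NA	NA
Anopheles1	Chryseobacterium_1	9.14	1.74	NA	NA
Anopheles1	Acinetobacter_1	6.36	2.36	NA	NA
Anopheles1	Acinetobacter_2	3.55	5.31	NA	NA
Anopheles1	Serratia_1	3.53	5.04	NA	NA
Anopheles1	Stenotrophomonas_1	3.26	1.61	NA	NA
Anopheles1	Enhydrobacter_1	1.82	3.16	NA	NA
Anopheles1	Thorsellia_1	1.54	3.06	NA	NA
Anopheles1	Enhydrobacter_2	1.38	0.23	NA	NA
Anopheles1	Pseudomonas_1	1.36	1.4	NA	NA
Anopheles1	Acinetobacter_3	1.17	0.11	NA	NA
Anopheles2	Sphingomonas_1	35.85	0.01	0.0038	0.00121
Anopheles2	Acinetobacter_1	21.94	4.36	5.74	5.01
Anopheles2	Caulobacter_1	19.83	0	0	0
Anopheles2	Escherichia-Shigella_1	8.26	2.09	2.23	2.27
Anopheles2	Cloacibacterium_1	4.46	0.86	1.02	0.99
Anopheles2	Acinetobacter_2	1.67	0.14	0.11	0.14
Anopheles2	Diaphorobacter_1	1.08	0.18	0.22	0.21
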