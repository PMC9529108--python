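study_id	author	year	country	race_group	genotyping_method	snp	case_n11	case_n12	case_n22	ctrl_n11	ctrl_n12	ctrl_n22	quality_score
Raljevic-2021	Raljevic	2021	Croatia	White	PCR-RFLP	rs2228570	50	84	21	34	52	18	9
Fronczek-2021	Fronczek	2021	Poland	White	PCR-Taqman	rs2228570	105	186	95	139	242	78	9
Ma-2020	Ma	2020	China	Asian	PCR-RFLP	rs2228570	44	88	6	344	161	16	9
Moradi-2017	Moradi	2017	Iran	White	PCR-RFLP	rs2228570	44	15	45	42	4	23	7
Maia-2016	Maia	2016	Brazil	White	PCR-Taqman	rs2228570	12	4	2	34	38	10	8
Maaty-2016	Maaty	2016	Egypt	African	PCR-Taqman	rs2228570	52	31	15	24	13	18	7
He-2015	He	2015	China	Asian	PCR-ABD	rs2228570	61	103	51	28	27	12	9
Hossein-Nezhad-1-2014	Hossein-Nezhad 1	2014	Iran	White	PCR-RFLP	rs2228570	104	82	16	76	34	8	9
Hossein-Nezhad-2-2014	Hossein-Nezhad 2	2014	Iran	White	PCR-RFLP	rs2228570	82	74	12	76	34	8	8
Hossein-Nezhad-3-2014	Hossein-Nezhad 3	2014	Iran	White	PCR-RFLP	rs2228570	152	98	22	76	34	8	9
Pan-2009	Pan	2009	China	Asian	PCR-RFLP	rs2228570	47	65	40	68	97	47	9
Raljevic-2021	Raljevic	2021	Croatia	White	PCR-RFLP	rs1544410	72	60	23	39	59	6	8
Ma-2020	Ma	2020	China	Asian	PCR-RFLP	rs1544410	115	19	4	443	63	15	9
Kiani-2019	Kiani	2019	Iran	White	PCR-RFLP	rs1544410	40	69	48	69	79	34	8
Moradi-2017	Moradi	2017	Iran	White	PCR-RFLP	rs1544410	43	17	44	38	3	28	7
Ferrarezi-1-2013	Ferrarezi 1	2013	Brazil	White	PCR-ABD	rs1544410	154	242	86	969	1261	425	9
Ferrarezi-2-2013	Ferrarezi 2	2013	Brazil	White	PCR-ABD	rs1544410	138	246	81	986	1256	430	9
Ferrarezi-3-2013	Ferrarezi 3	2013	Brazil	White	PCR-ABD	rs1544410	248	418	139	875	1084	373	9
Ferrarezi-4-2013	Ferrarezi 4	2013	Brazil	White	PCR-ABD	rs1544410	64	119	47	151	251	81	9
Pan-2009	Pan	2009	China	Asian	PCR-RFLP	rs1544410	2	21	129	4	38	170	8
Ortlepp-2003	Ortlepp	2003	Germany	White	PCR-RFLP	rs1544410	249	794	481	124	419	232	7
Fronczek-2021	Fronczek	2021	Poland	White	PCR-Taqman	rs7975232	97	196	93	114	213	129	9
Ma-2020	Ma	2020	China	Asian	PCR-RFLP	rs7975232	58	63	17	203	224	94	9
Moradi-2017	Moradi	2017	Iran	White	PCR-RFLP	rs7975232	57	10	37	38	9	22	7
He-2015	He	2015	China	Asian	PCR-ABD	rs7975232	7	29	31	18	93	104	8
Maaty-2015	Maaty	2015	Egypt	African	PCR-Taqman	rs7975232	38	63	36	22	22	14	8
Ferrarezi-1-2013	Ferrarezi 1	2013	Brazil	White	PCR-ABD	rs7975232	137	235	112	679	1369	605	9
Ferrarezi-2-2013	Ferrarezi 2	2013	Brazil	White	PCR-ABD	rs7975232	120	248	97	697	1355	620	9
Ferrarezi-3-2013	Ferrarezi 3	2013	Brazil	White	PCR-ABD	rs7975232	215	414	176	602	1189	541	9
Ferrarezi-4-2013	Ferrarezi 4	2013	Brazil	White	PCR-ABD	rs7975232	86	101	42	135	229	118	9
Raljevic-2021	Raljevic	2021	Croatia	White	PCR-RFLP	rs731236	76	57	22	45	54	5	8
Fronczek-2021	Fronczek	2021	Poland	White	PCR-Taqman	rs731236	152	180	54	188	209	62	9
Ma-2020	Ma	2020	China	Asian	PCR-RFLP	rs731236	39	94	5	333	172	16	9
Moradi-2017	Moradi	2017	Iran	White	PCR-RFLP	rs731236	52	18	34	33	10	26	7
Maia-2016	Maia	2016	Brazil	White	PCR-Taqman	rs731236	8	7	3	37	39	6	8
He-2015	He	2015	China	Asian	PCR-ABD	rs731236	195	20	0	63	4	0	9
Maaty-2015	Maaty	2015	Egypt	African	PCR-Taqman	rs731236	36	60	41	18	27	13	8
Ferrarezi-1-2013	Ferrarezi 1	2013	Brazil	White	PCR-ABD	rs731236	163	240	81	982	1266	406	9
Ferrarezi-2-2013	Ferrarezi 2	2013	Brazil	White	PCR-ABD	rs731236	153	247	66	994	1256	422	9
Ferrarezi-3-2013	Ferrarezi 3	2013	Brazil	White	PCR-ABD	rs731236	265	415	126	881	1089	361	9
Ferrarezi-4-2013	Ferrarezi 4	2013	Brazil	White	PCR-ABD	rs731236	80	110	40	199	212	73	9
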