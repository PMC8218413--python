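sn	gene_id	locus_id	chromosome	start	end	orf_bp	exon_count	protein_length_aa	mw_da	pi	tm_count	subfamily
1	CaAAP1	Capana07g002429	Chr07	220179435	220181692	1335	7	444	49460.8	8.72	11	AAP
2	CaAAP2	Capana07g002430	Chr07	220188828	220192330	1869	10	622	68584.1	8.46	14	AAP
3	CaAAP3	Capana07g002431	Chr07	220195003	220198004	1410	7	469	51763.2	8.45	10	AAP
4	CaAAP4	Capana07g002432	Chr07	220225817	220233681	2532	13	843	93224.4	8.88	17	AAP
5	CaAAP5	Capana04g000780	Chr04	14469803	14475148	1446	7	481	52757.7	8.81	10	AAP
6	CaAAP6	Capana12g000826	Chr12	27187513	27194231	1467	7	488	53825.3	8.94	9	AAP
7	CaAAP7	Capana08g002210	Chr08	143014796	143019992	1419	7	472	51747.8	9.12	11	AAP
8	CaAAP8	Capana04g001588	Chr04	67204663	67207202	1434	6	477	52413.8	8.27	10	AAP
9	CaAAP9	Capana06g001752	Chr06	50038242	50040303	1419	6	472	51681.9	7.84	10	AAP
10	CaAAP10	Capana05g001770	Chr05	174328892	174330262	1020	3	339	37207.9	6.86	7	AAP
11	CaLHT1	Capana02g003614	Chr02	162887482	162890584	1350	8	449	50428.0	8.6	9	LHT
12	CaLHT2	Capana02g003615	Chr02	162905774	162912940	1266	7	421	47443.0	8.24	9	LHT
13	CaLHT3	Capana02g003616	Chr02	162914284	162921151	1332	8	443	49858.6	9.08	11	LHT
14	CaLHT4	Capana04g002888	Chr04	215599914	215604069	1227	9	408	46113.8	8.27	7	LHT
15	CaLHT5	Capana04g001881	Chr04	130533897	130536648	1329	6	442	49917.6	8.06	10	LHT
16	CaLHT6	Capana11g000230	Chr11	5761051	5762379	1329	1	442	49944.5	9.1	10	LHT
17	CaLHT7	Capana03g001379	Chr03	25005836	25008812	1329	7	442	49012.6	9.4	11	LHT
18	CaLHT8	Capana05g000336	Chr05	7406911	7414486	1065	7	354	39858.5	9.42	7	LHT
19	CaLHT9	Capana11g002248	Chr11	216341951	216346445	1311	8	436	48573.9	9.03	8	LHT
20	CaLHT10	Capana04g000478	Chr04	7738487	7744000	1581	5	526	57977.4	9.61	9	LHT
21	CaLHT11	Capana04g000098	Chr04	1109665	1112218	1338	5	445	49110.6	8.68	10	LHT
22	CaLHT12	Capana08g002793	Chr08	152269921	152272976	1713	5	570	61963.0	9.55	9	LHT
23	CaLHT13	Capana11g000398	Chr11	11019799	11021033	708	2	235	25865.9	9.01	2	LHT
24	CaLHT14	Capana04g000106	Chr04	1178475	1183677	669	2	222	24427.3	8.47	3	LHT
25	CaGAT1	Capana00g003418	Chr00	545297054	545303475	1365	7	454	49950.5	8.68	10	GAT
26	CaGAT2	Capana11g000210	Chr11	5435275	5440152	1092	6	363	39923.8	9.98	9	GAT
27	CaProT1	Capana05g001989	Chr05	191409867	191415970	1320	7	439	47836.8	9.73	12	ProT
28	CaProT2	Capana05g001990	Chr05	191424542	191430181	1347	7	448	49162.1	9.4	11	ProT
29	CaProT3	Capana03g002827	Chr03	118029421	118036334	1344	7	447	49190.2	9.61	12	ProT
30	CaAUX1	Capana09g001555	Chr09	181029189	181033262	1467	7	488	54841.3	8.15	10	AUX
31	CaAUX2	Capana10g001370	Chr10	147549183	147556929	1467	7	488	54912.8	8.56	10	AUX
32	CaAUX3	Capana04g001744	Chr04	99262090	99266939	1317	8	438	49663.3	8.25	9	AUX
33	CaAUX4	Capana08g002704	Chr08	150979738	150984984	1482	8	493	55541.5	8.75	10	AUX
34	CaANT1	Capana02g002432	Chr02	144978448	144979728	1281	1	426	46665.9	7.92	11	ANT
35	CaANT2	Capana02g002433	Chr02	144981268	144982602	1335	1	444	48548.7	4.74	11	ANT
36	CaANT3	Capana02g002434	Chr02	144983909	144985192	1284	1	427	46457.5	4.82	11	ANT
37	CaANT4	Capana04g002414	Chr04	201839016	201840293	1278	1	425	46811.9	7.45	11	ANT
38	CaANT5	Capana03g004210	Chr03	248829547	248830964	930	2	309	33786.3	10.06	10	ANT
39	CaATL1	Capana06g001998	Chr06	75940086	75942122	846	3	281	30550.9	4.94	3	ATLa
40	CaATL2	Capana03g000522	Chr03	7178172	7179590	1419	1	472	51153.5	5.43	10	ATLa
41	CaATL3	Capana05g002081	Chr05	197860240	197862960	1302	6	433	47459.1	8.35	11	ATLa
42	CaATL4	Capana00g004937	Chr00	676629079	676631743	1320	5	439	47898.6	8.55	11	ATLa
43	CaATL5	Capana04g000715	Chr04	12477359	12484737	1344	5	447	48657.5	8.36	11	ATLa
44	CaATL6	Capana02g000804	Chr02	93929776	93933801	1407	5	468	50795.2	8.78	11	ATLa
45	CaATL7	Capana02g003206	Chr02	157224580	157228911	1383	5	460	49954.5	8.55	11	ATLa
46	CaVAAT1	Capana00g004212	Chr00	618994856	618996151	1296	1	431	46618.7	7.96	8	ATLb
47	CaVAAT2	Capana04g001726	Chr04	93008498	93010474	1281	3	426	46958.9	7.71	10	ATLb
48	CaVAAT3	Capana12g002556	Chr12	222093246	222094767	1017	2	338	36992.0	7.91	9	ATLb
49	CaVAAT4	Capana05g002349	Chr05	207916251	207920239	1140	3	379	41865.5	9.04	9	ATLb
50	CaVAAT5	Capana03g003057	Chr03	162840327	162847744	1395	9	464	51484.7	4.27	7	ATLb
51	CaVAAT6	Capana10g001696	Chr10	173666186	173669984	1608	11	535	57908.7	5.19	10	ATLb
52	CaVAAT7	Capana03g002859	Chr03	127734852	127743213	1338	7	445	48690.8	4.98	5	ATLb
53	CaVAAT8	Capana12g002523	Chr12	220748120	220761121	1989	15	662	73214.4	5.85	8	ATLb
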