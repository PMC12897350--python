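marker	order	predictor_index	wavelength_nm	weight	coefficient
acidity	1	347	1792	0.36	-25.88
acidity	2	247	1592	0.26	27.0
acidity	3	129	1356	0.55	-109.59
acidity	4	509	2116	0.37	-7.21
acidity	5	44	1186	0.18	-36.34
acidity	6	318	1734	0.1	4.89
acidity	7	72	1242	0.17	-108.59
acidity	8	45	1188	0.15	230.9
acidity	9	133	1364	0.12	-98.56
acidity	10	436	1970	0.16	15.64
acidity	11	265	1628	0.17	198.39
acidity	12	339	1776	0.12	27.86
acidity	13	377	1852	0.11	-61.27
acidity	14	2	1102	0.1	81.84
acidity	15	305	1708	0.12	-14.97
acidity	16	307	1712	0.13	45.22
acidity	17	306	1710	0.11	25.26
acidity	18	563	2224	0.1	14.67
acidity	19	153	1404	0.09	-62.17
acidity	20	667	2432	0.09	-3.77
acidity	21	555	2208	0.09	-48.99
acidity	22	308	1714	0.08	-18.86
acidity	23	237	1572	0.06	-175.87
k232	1	147	1392	0.73	-109.72
k232	2	186	1470	0.41	140.07
k232	3	662	2422	0.15	-23.88
k232	4	378	1854	0.11	74.87
k232	5	116	1330	0.13	106.25
k232	6	158	1414	0.16	140.69
k232	7	338	1774	0.17	-56.95
k232	8	182	1462	0.11	-709.78
k232	9	337	1772	0.1	169.81
k232	10	634	2366	0.1	-28.8
k232	11	578	2254	0.11	46.75
k232	12	648	2394	0.09	-36.0
k232	13	142	1382	0.08	-261.38
k232	14	323	1744	0.08	-63.92
k232	15	305	1708	0.08	-23.14
k232	16	309	1716	0.08	110.93
k232	17	348	1794	0.08	-214.07
k232	18	666	2430	0.1	-46.45
k232	19	292	1682	0.07	54.5
k232	20	521	2140	0.08	-39.7
k232	21	134	1366	0.07	-1023.57
k232	22	573	2244	0.06	66.97
k232	23	594	2286	0.06	-32.91
k232	24	605	2308	0.08	88.33
k232	25	386	1870	0.06	306.32
k232	26	387	1872	0.06	-708.12
k232	27	127	1352	0.06	1112.35
k270	1	508	2114	0.78	42.57
k270	2	403	1904	0.38	-6.07
k270	3	695	2488	0.18	-16.03
k270	4	39	1176	0.14	-57.43
k270	5	396	1890	0.08	66.89
k270	6	574	2246	0.07	15.55
k270	7	648	2394	0.06	-12.37
k270	8	578	2254	0.09	33.7
k270	9	573	2244	0.07	-30.71
k270	10	691	2480	0.06	27.11
k270	11	472	2042	0.05	4.1
k270	12	49	1196	0.17	-157.5
k270	13	457	2012	0.11	183.41
k270	14	455	2008	0.12	-666.19
k270	15	467	2032	0.11	-469.33
k270	16	521	2140	0.1	-43.14
k270	17	503	2104	0.1	-228.13
k270	18	292	1682	0.09	97.37
k270	19	661	2420	0.08	21.5
k270	20	632	2362	0.07	-20.71
k270	21	476	2050	0.06	325.89
k270	22	694	2486	0.06	-61.42
k270	23	298	1694	0.06	-92.12
k270	24	515	2128	0.06	58.74
k270	25	491	2080	0.05	104.87
k270	26	497	2092	0.05	-474.02
k270	27	310	1718	0.05	21.33
delta_k	1	510	2118	0.84	5.22
delta_k	2	416	1930	0.29	-2.08
delta_k	3	414	1926	0.14	32.34
delta_k	4	526	2150	0.13	-2.66
delta_k	5	542	2182	0.16	10.96
delta_k	6	516	2130	0.1	5.81
delta_k	7	509	2116	0.08	34.28
delta_k	8	569	2236	0.07	-3.43
delta_k	9	326	1750	0.09	3.25
delta_k	10	306	1710	0.08	-6.23
delta_k	11	485	2068	0.1	6.89
delta_k	12	507	2112	0.1	-71.66
delta_k	13	413	1924	0.09	56.49
delta_k	14	309	1716	0.09	11.25
delta_k	15	670	2438	0.05	-1.23
delta_k	16	304	1706	0.06	-6.86
pv	1	139	1376	0.32	-800.99
pv	2	209	1516	0.48	2534.35
pv	3	223	1544	0.24	-4444.35
pv	4	340	1778	0.23	392.88
pv	5	41	1180	0.18	-761.72
pv	6	181	1460	0.28	-1125.42
pv	7	670	2438	0.22	-237.25
pv	8	461	2020	0.18	836.18
pv	9	186	1470	0.19	9138.76
pv	10	349	1796	0.18	957.84
pv	11	211	1520	0.12	-14347.13
pv	12	224	1546	0.12	10930.75
pv	13	326	1750	0.12	-417.96
pv	14	625	2348	0.12	141.39
pv	15	636	2370	0.1	-205.15
pv	16	210	1518	0.09	-12204.49
pv	17	689	2476	0.09	-173.08
pv	18	586	2270	0.1	-358.99
pv	19	601	2300	0.09	-800.99
pv	20	604	2306	0.1	2534.35
pv	21	207	1512	0.09	-4444.35
pv	22	311	1720	0.09	392.88
pv	23	607	2312	0.08	-761.72
pv	24	614	2326	0.08	-1125.42
pv	25	603	2304	0.09	-237.25
pv	26	691	2480	0.08	836.18
pv	27	226	1550	0.07	9138.76
pv	28	465	2028	0.09	957.84
pv	29	357	1812	0.1	-14347.13
pv	30	367	1832	0.08	10930.75
anv	1	147	1392	0.65	-2139.32
anv	2	436	1970	0.49	3945.58
anv	3	632	2362	0.14	-378.3
anv	4	158	1414	0.12	901.97
anv	5	378	1854	0.11	2232.23
anv	6	120	1338	0.22	3987.53
anv	7	678	2454	0.12	716.74
anv	8	41	1180	0.1	-3330.91
anv	9	143	1384	0.08	6173.8
anv	10	500	2098	0.09	-1536.66
anv	11	578	2254	0.08	651.67
anv	12	246	1590	0.08	6199.57
anv	13	231	1560	0.09	-25831.9
anv	14	306	1710	0.09	-525.99
anv	15	307	1712	0.08	1516.8
anv	16	265	1628	0.08	5421.99
anv	17	305	1708	0.14	-3297.27
anv	18	437	1972	0.08	-18201.29
anv	19	129	1356	0.08	-24289.36
anv	20	269	1636	0.07	17533.14
anv	21	303	1704	0.07	-1422.31
anv	22	28	1154	0.09	10124.97
anv	23	333	1764	0.08	-2619.12
anv	24	237	1572	0.07	-32047.14
anv	25	111	1320	0.08	-25503.1
anv	26	154	1406	0.06	-9077.43
anv	27	72	1242	0.07	-14594.19
anv	28	73	1244	0.07	30340.46
anv	29	150	1398	0.07	23577.69
anv	30	252	1602	0.06	28613.07
totox	1	148	1394	0.55	-2355.09
totox	2	436	1970	0.55	6063.79
totox	3	653	2404	0.14	-746.72
totox	4	578	2254	0.12	1201.14
totox	5	633	2364	0.15	-1190.38
totox	6	378	1854	0.09	2575.18
totox	7	249	1596	0.18	4790.37
totox	8	41	1180	0.17	-8532.07
totox	9	579	2256	0.09	-1499.6
totox	10	584	2266	0.1	1030.04
totox	11	597	2292	0.11	-2993.93
totox	12	601	2300	0.08	3237.23
totox	13	586	2270	0.09	-2698.39
totox	14	606	2310	0.07	2828.94
totox	15	604	2306	0.08	-4273.12
totox	16	248	1594	0.06	-37674.22
totox	17	594	2286	0.05	-2453.66
totox	18	591	2280	0.08	4671.52
totox	19	610	2318	0.06	2308.8
totox	20	593	2284	0.06	-2615.21
totox	21	596	2290	0.06	3195.97
totox	22	603	2304	0.06	3438.93
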