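no	name	ri	rt_s	drift_time_ms	volume_a	volume_b	volume_c
1	(+)-Limonene	1189.3	433.309	1.65766	47.32	21.00	18.45
2	1,2-Ethanediol	1611.1	1224.033	1.15889	193.75	156.70	307.64
3	1-Butanol-D	1150.3	376.987	1.3813	1348.39	1055.02	1285.03
4	1-Butanol-M	1150.8	377.739	1.18107	120.26	102.56	132.41
5	1-Butanol, 3-methyl-, acetate	1098.9	313.929	1.29261	94.11	55.98	48.65
6	1-Hexanal-D	1092.5	307.402	1.5605	2004.85	1105.25	812.02
7	1-Hexanal-M	1090.7	305.662	1.2717	410.76	168.15	199.22
8	1-Hexanol-D	1370.6	730.557	1.32995	2577.51	1732.20	1479.16
9	1-Hexanol-M	1368.9	727.847	1.6473	858.88	403.07	317.09
10	1-Octen-3-ol	1476.4	916.663	1.1603	140.36	152.57	455.21
11	1-Pentanol-D	1257.5	546.758	1.51302	3641.90	2330.38	2190.92
12	1-Pentanol-M	1258.7	548.929	1.25232	566.51	535.20	532.15
13	1-Propanol-D	1043.8	263.684	1.2563	1635.42	2108.75	2257.31
14	1-Propanol-M	1044.8	264.48	1.10846	77.39	82.29	62.42
15	2,3-Bbutanedione	927.4	190.575	1.17797	2020.23	2355.91	2300.38
16	2,6-Dimethyl pyrazine-D	1359.2	712.777	1.53432	96.20	87.06	325.36
17	2,6-Dimethyl pyrazine-M	1359.4	713.102	1.14292	42.39	39.75	82.61
18	2-Acetylpyridine	1569.9	1120.373	1.11215	138.31	152.23	372.34
19	2-Butanone	912	183.29	1.24516	1833.67	1415.23	1477.38
20	2-Heptanone-D	1192	437.464	1.62967	979.16	439.76	427.46
21	2-Heptanone-M	1188.7	432.325	1.26116	853.13	439.76	521.98
22	2-Hexanone-D	1097	311.827	1.50233	537.91	431.80	459.12
23	2-Hexanone-M	1095	309.868	1.19273	449.86	393.95	430.29
24	(E)-2-Hhexen-1-ol	1348.6	696.854	1.17499	186.52	159.96	159.59
25	2-Methylbutanoic acid, methyl ester	1028.1	250.954	1.18974	241.93	282.58	220.97
26	2-Methylpyrazine	1292.7	616.299	1.06994	894.63	288.30	321.60
27	2-Nonanone-D	1398	774.751	1.88186	49.58	47.39	49.36
28	2-Nonanone-M	1401.7	780.967	1.87851	43.77	42.12	39.74
29	2-Octanone-D	1295	621.087	1.75701	368.72	282.99	311.93
30	2-Octanone-M	1292.4	615.705	1.33009	88.85	88.59	90.09
31	2-Pentanone	996	226.78	1.3725	109.65	56.16	64.99
32	2-Propanol	920.1	187.091	1.22384	1142.23	1759.81	1455.53
33	3-Methyl butyl acetate	1149.9	376.536	1.31347	53.16	29.85	34.89
34	Acetic acid	1477.7	919.242	1.0518	2331.29	2504.44	4153.42
35	Acetic acid ethyl ester-D	914.3	184.354	1.32401	348.72	316.74	274.78
36	Acetic acid ethyl ester-M	918.1	186.15	1.09431	56.30	23.46	35.04
37	Acetophenone-D	1688.5	1445.218	1.17229	988.12	1180.18	4038.73
38	Acetophenone-M	1688	1443.765	1.38686	44.25	54.32	115.64
39	α-Pinene	992.3	224.692	1.29579	221.34	157.79	169.56
40	Benzaldehyde	1565.4	1109.612	1.14581	200.18	124.63	161.89
41	Butanal	894.9	175.517	1.28753	44.73	35.52	39.40
42	Butanoic acid, ethyl ester	1018.6	243.498	1.56902	171.15	179.31	126.95
43	Cyclohexanone	1292.1	614.912	1.15711	184.07	77.66	83.86
44	Ethanol	939.2	196.365	1.13225	3471.54	3298.02	3895.87
45	Ethyl acrylate	1025.7	249.08	1.41748	36.99	37.05	39.45
46	Ethyl butanoate	991	223.924	1.19944	1327.66	714.71	558.32
47	Ethyl hexanoate-D	1241.7	517.989	1.33922	361.29	366.11	920.86
48	Ethyl hexanoate-M	1242.7	519.833	1.78996	187.21	163.97	313.61
49	Ethyl octanoate	1401.9	781.337	1.47904	452.88	429.68	319.57
50	Ethyl pentanoate	1172.2	407.663	1.26934	121.34	88.84	99.17
51	Heptanal	1131.5	352.605	1.31628	30.45	24.15	26.67
52	n-Pentanal	990.2	223.486	1.41859	370.03	94.34	55.40
53	Propanal-D	791.5	135.056	1.06433	422.97	489.08	569.58
54	Propanal-M	790.4	134.684	1.14053	601.24	489.08	435.88
55	Styrene	1296.4	623.002	1.41216	326.33	208.17	181.32
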