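abbrev	motif_size	n_loci	total_bp	rel_abundance	rel_density	coverage_pct	gc_bp	gc_pct
Amex	1	170345	3398972	189.44	3753.31	0.38	266645	7.84
Amex	2	446448	12194636	498.90	13549.68	1.36	3706651	30.40
Amex	3	61775	2572995	69.16	2833.21	0.29	333193	12.95
Amex	4	84721	3160820	95.30	3525.04	0.35	884624	27.99
Amex	5	16919	1094190	18.90	1187.90	0.12	282448	25.81
Amex	6	2179	193794	2.43	209.55	0.02	60384	31.16
Amex	total	782387	22615407	874.13	25058.69	2.52	5533945	24.47
Ccar	1	186935	2883267	230.83	3558.04	0.37	84049	2.91
Ccar	2	181614	5801364	224.78	7173.27	0.72	2057824	35.47
Ccar	3	53774	1273065	66.86	1588.10	0.16	127770	10.04
Ccar	4	62915	1749772	77.78	2162.41	0.22	374219	21.39
Ccar	5	15817	686070	19.57	850.94	0.08	79829	11.64
Ccar	6	1724	69300	2.13	88.33	0.01	20736	29.92
Ccar	total	502779	12462838	621.95	15421.09	1.56	2744427	22.02
Drer	1	207951	3278888	155.12	2445.81	0.24	156865	4.78
Drer	2	382761	14766368	285.51	11014.63	1.10	3485035	23.60
Drer	3	140175	3374835	104.56	2517.38	0.25	262890	7.79
Drer	4	243740	8195596	181.81	6113.32	0.61	2326652	28.39
Drer	5	35377	1419895	26.39	1059.14	0.11	104811	7.38
Drer	6	2080	58950	1.55	43.97	0.00	19507	33.09
Drer	total	1012084	31094532	754.94	23194.25	2.31	6355760	20.44
Csem	1	97303	1483637	232.06	3539.85	0.35	231161	15.58
Csem	2	127607	2668806	2998.81	6238.79	0.63	1071149	40.14
Csem	3	48581	1052241	114.46	2478.47	0.25	408981	38.87
Csem	4	34100	768504	79.96	1807.35	0.18	277262	36.08
Csem	5	5828	186075	13.57	428.73	0.04	54885	29.50
Csem	6	2996	106962	7.08	252.92	0.03	50107	48.85
Csem	total	316415	6266225	3445.94	14746.11	1.48	2093545	33.41
Eluc	1	45139	667053	62.88	928.80	0.08	326439	48.94
Eluc	2	150812	3215024	212.80	4533.65	0.41	1466606	45.62
Eluc	3	11632	208425	15.88	284.64	0.03	62534	30.03
Eluc	4	21952	411372	30.05	562.93	0.05	191704	46.60
Eluc	5	1140	26200	1.55	35.77	0.00	11874	45.32
Eluc	6	712	23232	1.01	33.21	0.00	11962	51.49
Eluc	total	231387	4551306	324.17	6379.00	0.57	2071119	45.51
Ipun	1	176856	2991388	237.37	4013.86	0.40	343854	11.49
Ipun	2	359022	10686166	484.03	14362.27	1.42	3777407	35.35
Ipun	3	91842	2466039	123.29	3302.90	0.32	324772	13.17
Ipun	4	108518	2422148	145.59	3347.91	0.32	526093	21.72
Ipun	5	9556	234630	12.84	315.11	0.03	50793	21.65
Ipun	6	1671	44820	2.24	59.92	0.01	15581	34.76
Ipun	total	747465	18845191	1005.36	25401.97	2.50	5038500	26.74
Locu	1	26639	347118	39.34	517.74	0.04	80197	23.10
Locu	2	16853	289242	30.03	527.85	0.03	122671	42.41
Locu	3	26590	644715	35.80	822.92	0.08	93309	14.47
Locu	4	4439	92396	7.76	153.69	0.01	35673	38.61
Locu	5	2292	56690	3.10	73.65	0.01	20527	36.21
Locu	6	1565	53070	1.84	62.81	0.01	23037	43.41
Locu	total	78378	1483231	117.87	2158.66	0.18	375414	25.31
Nfur	1	50594	805921	71.06	1131.40	0.11	364314	45.20
Nfur	2	186289	6543766	261.89	9175.17	0.91	3065853	46.85
Nfur	3	39742	918591	55.80	1288.97	0.13	221669	24.13
Nfur	4	55909	1531664	78.34	2142.29	0.21	530688	34.65
Nfur	5	10079	275340	14.04	382.28	0.04	76366	27.74
Nfur	6	1664	44028	2.33	61.70	0.01	20000	45.42
Nfur	total	344277	10119310	483.46	14181.81	1.41	4278890	42.28
Olat	1	76805	1120875	131.94	1925.44	0.19	198155	17.68
Olat	2	25449	515736	43.72	885.93	0.09	203111	39.38
Olat	3	15732	295236	27.02	507.16	0.05	104498	35.39
Olat	4	22084	776628	37.94	1334.10	0.13	250470	32.25
Olat	5	4973	145115	8.54	249.28	0.02	36644	25.25
Olat	6	485	13884	0.83	23.85	0.00	5484	39.50
Olat	total	145528	2867474	249.99	4925.76	0.48	798362	27.84
Okis	1	96581	1542599	59.64	952.88	0.09	993999	64.44
Okis	2	502660	12625074	310.50	7784.45	0.78	6023864	47.71
Okis	3	34901	643725	21.72	401.60	0.04	213491	33.16
Okis	4	90546	2527184	55.65	1551.12	0.16	1163069	46.02
Okis	5	17343	428935	10.64	263.32	0.03	166246	38.76
Okis	6	5178	169488	3.20	104.70	0.01	85527	50.46
Okis	total	747209	17937005	461.35	11058.07	1.11	8646196	48.20
Omyk	1	90887	1336990	51.64	759.16	0.08	690373	51.64
Omyk	2	390181	11517856	225.44	7684.48	0.66	5186111	45.03
Omyk	3	37290	704511	21.39	404.12	0.05	210431	29.87
Omyk	4	70423	1850584	40.46	1062.57	0.11	826372	44.65
Omyk	5	13985	342135	7.96	194.80	0.02	122566	35.82
Omyk	6	4590	140352	2.66	81.33	0.01	71447	50.91
Omyk	total	607356	15892428	349.55	10186.46	0.93	7107300	44.72
Onil	1	85303	1316072	98.69	1522.59	0.15	139335	10.59
Onil	2	123095	3294102	142.41	3811.02	0.38	1337732	40.61
Onil	3	33649	662808	38.93	766.82	0.08	166799	25.17
Onil	4	32971	731160	38.14	845.90	0.08	210529	28.79
Onil	5	12089	316950	13.99	366.69	0.04	69140	21.81
Onil	6	966	26856	1.12	31.07	0.00	8832	32.89
Onil	total	288073	6347948	333.28	7344.09	0.73	1932367	30.44
Pret	1	119330	1775344	188.83	2810.96	0.23	66159	3.73
Pret	2	70237	1810180	110.24	2843.81	0.28	858108	47.40
Pret	3	24815	616578	39.01	966.24	0.10	144894	23.50
Pret	4	32055	1138844	50.22	1777.93	0.18	421839	37.04
Pret	5	3815	125295	5.97	195.30	0.02	32651	26.06
Pret	6	786	21594	1.23	33.73	0.00	11193	51.83
Pret	total	251038	5487835	395.50	8627.97	0.81	1534844	27.97
Trub	1	34748	504976	129.25	1878.28	0.19	264888	52.46
Trub	2	63408	12729440	235.85	6432.72	4.73	837010	6.58
Trub	3	12671	262275	47.13	975.54	0.10	117321	44.73
Trub	4	16187	541848	60.21	2015.43	0.20	231326	42.69
Trub	5	3871	164760	14.40	612.83	0.06	87874	53.33
Trub	6	1127	34446	4.19	128.12	0.01	18573	53.92
Trub	total	132012	14237745	491.03	12042.92	5.29	1556992	10.94
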