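abbrev	region	mono	di	tri	tetra	penta	hexa
Amex	all	21.75	57.0	7.29	10.88	2.17	0.28
Amex	intergenic	1.05	3.26	0.53	0.77	0.16	0.04
Amex	intron	20.03	52.99	6.84	9.89	1.97	0.23
Amex	exon	0.68	0.81	0.52	0.17	0.03	0.01
Ccar	all	37.18	36.12	10.71	2.5	13.15	0.34
Ccar	intergenic	0.54	0.6	0.17	0.19	0.05	0.01
Ccar	intron	36.2	35.16	10.21	2.22	3.08	0.33
Ccar	exon	0.44	0.37	0.32	0.1	10.02	0.01
Drer	all	20.54	37.82	13.85	24.08	3.5	0.21
Drer	intergenic	2.1	5.66	1.79	3.42	0.4	0.02
Drer	intron	18.06	31.55	11.72	20.54	3.1	0.18
Drer	exon	0.39	0.6	0.34	0.12	0.01	0.0
Csem	all	31.05	39.78	15.25	11.11	1.85	0.96
Csem	intergenic	1.79	1.63	0.78	0.76	0.11	0.07
Csem	intron	27.47	37.29	12.76	9.72	1.66	0.8
Csem	exon	1.49	1.41	1.81	0.3	0.07	0.07
Eluc	all	19.51	65.18	5.03	9.49	0.49	0.31
Eluc	intergenic	1.1	3.45	0.33	0.7	0.06	0.04
Eluc	intron	17.19	60.03	3.92	8.54	0.42	0.26
Eluc	exon	1.22	1.7	0.78	0.25	0.01	0.01
Ipun	all	23.68	48.0	12.3	14.25	1.28	0.22
Ipun	intergenic	1.17	3.05	0.82	0.89	0.09	0.02
Ipun	intron	20.97	43.26	10.64	13.18	1.12	0.19
Ipun	exon	1.52	1.71	0.82	0.45	0.07	0.01
Locu	all	34.99	21.5	34.92	5.66	2.93	2.0
Locu	intergenic	6.57	4.81	7.46	1.26	0.73	0.51
Locu	intron	24.71	15.27	23.44	4.06	2.05	1.36
Locu	exon	2.71	1.42	3.01	0.35	0.14	0.13
Nfur	all	14.71	54.15	11.55	16.2	2.91	0.48
Nfur	intergenic	4.53	17.11	3.83	5.66	1.13	0.16
Nfur	intron	9.87	37.05	7.25	10.79	1.85	0.34
Nfur	exon	0.57	1.25	0.73	0.24	0.04	0.01
Olat	all	52.77	17.49	10.81	15.18	3.42	0.33
Olat	intergenic	6.26	2.19	1.37	2.21	0.55	0.05
Olat	intron	45.06	14.57	7.54	12.56	2.81	0.27
Olat	exon	1.45	0.73	1.9	0.4	0.06	0.02
Okis	all	12.85	67.38	4.61	12.15	2.31	0.7
Okis	intergenic	0.19	1.16	0.13	0.22	0.06	0.02
Okis	intron	12.29	65.73	4.17	11.84	2.23	0.68
Okis	exon	0.37	0.49	0.32	0.09	0.01	0.0
Omyk	all	14.91	64.33	6.12	11.59	2.29	0.75
Omyk	intergenic	0.26	1.27	0.24	0.3	0.11	0.04
Omyk	intron	14.17	61.7	5.27	11.22	2.18	0.7
Omyk	exon	0.57	1.27	0.63	0.24	0.02	0.02
Onil	all	29.61	42.73	11.68	11.45	4.2	0.34
Onil	intergenic	1.91	4.23	1.15	0.89	0.53	0.07
Onil	intron	25.15	36.73	9.01	10.02	3.55	0.24
Onil	exon	2.56	1.77	1.53	0.53	0.12	0.02
Pret	all	46.3	29.54	9.69	12.69	1.48	0.31
Pret	intergenic	2.25	2.01	0.59	0.1	0.12	0.03
Pret	intron	40.47	26.13	7.47	11.34	1.27	0.24
Pret	exon	3.58	1.39	1.63	0.36	0.09	0.04
Trub	all	26.32	48.03	9.6	12.26	2.93	0.85
Trub	intergenic	7.19	13.91	2.79	4.15	1.11	0.28
Trub	intron	17.07	32.71	5.4	7.81	1.78	0.52
Trub	exon	2.06	1.42	1.42	0.3	0.04	0.05
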