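species	abbrev	source	n_chromosomes	total_mbp	valid_mbp	n_pct
Astyanax mexicanus	Amex	Ensemble	25	930.61	896.76	3.75
Cyprinus carpio	Ccar	NCBI	50	825.07	809.20	1.91
Danio rerio	Drer	Ensemble	25	1345.10	1340.61	0.33
Cynoglossus semilaevis	Csem	Ensemble	22	445.14	424.00	5.28
Esox lucius	Eluc	Ensemble	24	796.47	787.67	1.12
Ictalurus punctatus	Ipun	Ensemble	29	762.01	752.24	1.29
Lepisosteus oculatus	Locu	Ensemble	29	891.14	834.92	9.31
Nothobranchius furzeri	Nfur	NCBI	19	1078.72	715.84	32.96
Oryzias latipes	Olat	Ensemble	24	723.44	582.14	19.51
Oncorhynchus kisutch	Okis	NCBI	30	1686.58	1628.60	3.43
Oncorhynchus mykiss	Omyk	NCBI	29	1949.96	1754.52	10.09
Oreochromis niloticus	Onil	Ensemble	23	868.59	864.36	0.49
Poecilia reticulata	Pret	Ensemble	23	696.70	637.75	8.43
Takifugu rubripes	Trub	Ensemble	22	281.57	268.85	4.64
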