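code	length	alr	max_saint	max_reverse	max_rosetta
1bmtA	246	0.1509	31.28	24.79	27.23
1hjrA	158	0.1777	42.33	31.00	37.67
1ji4A	144	0.1851	50.18	48.75	50.71
1k5nA	276	0.1997	18.08	18.37	16.35
1mf7A	194	0.2106	29.05	27.97	31.76
1n2zA	245	0.1668	20.26	18.21	20.37
1oaaA	259	0.1909	35.60	25.70	32.90
1qc7A	101	0.2762	70.12	67.38	62.20
1ryp2	233	0.2030	23.98	21.25	27.39
1rypI	222	0.3251	27.65	25.13	29.50
1tcaA	317	0.1592	22.27	18.09	22.45
1wehA	171	0.1635	33.18	28.87	31.55
1y1lA	124	0.2226	36.67	32.71	35.83
1yqgA	263	0.1723	26.74	22.10	27.41
1yw5A	177	0.1637	28.81	25.91	29.42
1zxxA	319	0.1576	19.60	15.95	18.10
2d00A	109	0.2345	53.32	45.92	50.77
2d1pB	119	0.1581	39.13	31.96	36.96
2ehgA	149	0.2088	46.03	31.03	33.62
2euiA	153	0.2054	42.88	41.54	45.96
2f1kA	279	0.1664	28.75	22.34	28.02
2g64A	140	0.1676	31.44	29.17	32.58
2h0rA	216	0.1555	20.05	20.89	25.85
2hy5A	130	0.1693	37.60	31.10	37.20
2imfA	203	0.1810	28.55	29.19	25.63
2jdjA	105	0.1666	41.84	38.16	50.26
2ocgA	254	0.1793	24.20	21.71	24.20
2pd2A	108	0.2397	52.12	50.47	55.42
2q35A	243	0.2346	23.52	19.09	20.46
2rcyA	262	0.1922	25.79	21.75	24.51
2rhwA	283	0.1538	21.88	17.77	21.25
3beoA	375	0.1637	16.41	14.29	16.48
3vubA	101	0.1550	70.31	39.06	52.34
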