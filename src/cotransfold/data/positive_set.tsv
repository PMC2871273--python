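code	length	alr	mean_saint	mean_reverse	mean_rosetta	max_saint	max_reverse	max_rosetta
1bmtA	246	0.1509	17.39	14.44	17.50	30.28	24.19	26.12
1hjrA	158	0.1777	21.56	19.06	21.75	41.77	30.06	35.76
1ji4A	144	0.1851	30.37	32.61	32.77	49.31	48.09	50.17
1k5nA	276	0.1997	10.96	10.58	11.03	16.94	17.21	15.58
1mf7A	194	0.2106	18.17	15.08	18.15	28.74	27.06	31.31
1n2zA	245	0.1668	14.04	12.05	14.12	20.41	17.24	21.43
1oaaA	259	0.1909	20.41	14.51	19.11	35.14	25.97	32.14
1qc7A	101	0.2762	39.69	34.93	41.31	63.12	61.63	55.94
1ryp2	233	0.2030	14.74	13.83	15.13	22.75	20.71	26.07
1rypI	222	0.3251	15.37	13.69	15.21	24.21	21.28	24.77
1tcaA	317	0.1592	11.32	8.58	10.70	19.32	15.69	19.56
1wehA	171	0.1635	19.21	18.56	19.36	32.89	28.22	31.14
1y1lA	124	0.2226	22.34	21.63	23.20	36.69	33.27	36.49
1yqgA	263	0.1723	17.23	13.66	17.04	26.62	21.77	27.09
1yw5A	177	0.1637	17.36	16.41	17.96	26.69	24.15	27.26
1zxxA	319	0.1576	11.67	9.73	11.63	19.20	15.75	17.87
2d00A	109	0.2345	31.79	23.93	31.22	49.77	42.20	47.25
2d1pB	119	0.1581	23.65	21.26	24.29	38.03	32.56	36.13
2ehgA	149	0.2088	21.74	19.51	21.80	44.97	30.54	32.72
2euiA	153	0.2054	22.07	21.29	22.67	38.73	36.76	40.20
2f1kA	279	0.1664	16.75	14.49	16.39	28.23	21.68	27.78
2g64A	140	0.1676	19.86	18.55	20.66	29.64	27.50	30.54
2h0rA	216	0.1555	13.77	15.35	14.57	21.18	23.03	27.78
2hy5A	130	0.1693	23.39	21.54	23.60	37.12	30.38	36.73
2imfA	203	0.1810	18.34	16.25	18.41	28.20	28.33	25.00
2j01V	101	0.1604	20.27	18.26	20.12	27.97	26.49	27.97
2jdjA	105	0.1666	23.39	21.53	24.07	39.05	35.00	45.71
2ocgA	254	0.1793	16.33	11.62	16.45	24.31	21.75	23.92
2pd2A	108	0.2397	30.66	28.83	30.82	51.62	49.54	54.86
2q35A	243	0.2346	13.77	13.24	13.98	23.05	19.14	20.37
2rcyA	262	0.1922	16.71	14.10	16.67	26.15	21.18	24.62
2rhwA	283	0.1538	12.66	10.58	13.52	21.73	17.67	21.20
3beoA	375	0.1637	10.18	8.42	10.21	15.93	13.67	16.07
3vubA	101	0.1550	25.75	22.37	25.62	67.57	37.62	51.24
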