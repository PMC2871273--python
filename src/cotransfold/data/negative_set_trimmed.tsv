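code	length	alr	max_saint	max_reverse	max_rosetta
1aocA	175	-0.2193	24.83	20.72	23.12
1aym1	285	-0.2877	11.54	10.02	12.45
1aym3	238	-0.1526	15.32	11.75	15.55
1ddlA	188	-0.2148	19.24	19.24	22.04
1dwkA	156	-0.1839	34.48	33.62	35.52
1dy5A	124	-0.1685	26.46	25.00	26.25
1e0cA	271	-0.1927	16.97	14.26	20.38
1kf6D	119	-0.1764	41.51	42.45	38.21
1kptA	105	-0.1756	34.84	30.32	32.98
1kyfA	247	-0.2037	20.27	18.80	20.48
1l7lA	121	-0.1779	21.37	20.94	22.65
1mkaA	171	-0.1794	25.64	26.91	25.96
1nekC	129	-0.2053	54.21	49.07	53.97
1p0zA	131	-0.1594	46.01	43.49	60.92
1qqp3	220	-0.3876	21.20	15.06	18.86
1seiA	130	-0.2636	41.47	36.31	41.27
1tt8A	164	-0.1881	25.32	24.52	26.61
1umhA	184	-0.1630	18.37	16.99	16.85
1uz3A	102	-0.1711	49.41	51.47	45.00
1wt9B	123	-0.1723	35.81	30.18	27.25
1y8cA	246	-0.1984	27.67	19.52	24.38
2ag4A	164	-0.2084	20.09	20.41	21.04
2awgA	118	-0.1693	31.65	25.46	33.26
2b0aA	186	-0.1747	23.33	20.15	21.97
2bnqD	203	-0.1799	26.24	20.44	22.93
2e56A	144	-0.1542	22.01	19.40	20.34
2edmA	161	-0.1638	18.28	18.28	18.10
2nwfA	141	-0.1601	35.04	29.56	34.31
2ov0A	105	-0.2059	29.17	31.25	30.95
2owpA	129	-0.1827	36.67	37.29	35.42
2p25A	126	-0.1604	48.08	46.37	58.12
2tgiA	112	-0.2279	26.21	28.88	29.61
3besR	250	-0.1606	17.58	16.36	16.77
3ezmA	101	-0.3241	37.37	36.86	35.82
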