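code	length	alr	mean_saint	mean_reverse	mean_rosetta	max_saint	max_reverse	max_rosetta
1aocA	175	-0.2193	14.48	14.41	14.96	21.57	19.57	20.43
1aym1	285	-0.2877	7.46	7.07	7.40	10.26	9.56	10.79
1aym3	238	-0.1526	9.19	7.92	9.26	13.97	10.71	13.97
1ddlA	188	-0.2148	10.87	10.50	10.95	16.09	15.69	17.69
1dwkA	156	-0.1839	20.23	18.97	20.29	32.05	32.37	33.17
1dy5A	124	-0.1685	17.07	16.77	17.48	26.41	25.60	25.40
1e0cA	271	-0.1927	11.53	9.48	12.36	16.61	13.01	18.82
1kf6D	119	-0.1764	25.06	24.13	25.44	38.03	38.66	34.45
1kptA	105	-0.1756	22.50	21.20	22.91	31.67	28.57	30.71
1kyfA	247	-0.2037	12.67	9.60	13.26	20.34	18.93	20.65
1l7lA	121	-0.1779	15.17	13.81	15.90	20.87	20.25	22.11
1mkaA	171	-0.1794	15.88	16.32	16.48	23.98	25.15	25.15
1nekC	129	-0.2053	27.71	26.88	28.98	44.77	42.05	45.93
1p0zA	131	-0.1594	31.27	27.99	33.13	42.75	40.84	58.21
1qqp3	220	-0.3876	10.10	8.60	10.13	16.25	11.70	14.77
1seiA	130	-0.2636	25.49	20.64	24.06	40.77	35.77	40.77
1tt8A	164	-0.1881	16.36	13.53	17.02	24.54	23.63	25.46
1umhA	184	-0.1630	11.68	10.31	11.83	17.93	16.71	16.58
1uz3A	102	-0.1711	28.90	31.22	29.49	41.42	43.87	39.46
1wt9B	123	-0.1723	21.70	18.90	21.60	37.20	29.88	30.49
1y8cA	246	-0.1984	15.77	11.56	15.09	27.54	19.51	23.98
2ag4A	164	-0.2084	13.61	11.99	13.86	19.66	19.82	20.58
2awgA	118	-0.1693	19.78	16.46	20.02	29.45	26.48	32.42
2b0aA	186	-0.1747	13.33	11.94	13.62	20.97	18.15	19.49
2bnqD	203	-0.1799	13.29	9.90	13.16	25.12	18.35	20.94
2e56A	144	-0.1542	14.06	13.85	14.21	21.53	19.27	19.27
2edmA	161	-0.1638	11.45	11.33	11.77	16.61	16.77	16.46
2nwfA	141	-0.1601	20.39	17.20	21.93	34.04	29.79	33.51
2ov0A	105	-0.2059	19.70	17.86	20.37	27.62	30.24	30.00
2owpA	129	-0.1827	22.61	21.33	23.30	34.69	35.47	34.69
2p25A	126	-0.1604	28.74	27.95	30.79	46.03	43.45	55.75
2tgiA	112	-0.2279	18.38	17.64	18.79	24.55	26.56	27.46
3besR	250	-0.1606	11.54	10.88	11.85	17.80	16.80	17.40
3ezmA	101	-0.3241	28.74	20.25	29.04	38.12	36.14	36.14
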