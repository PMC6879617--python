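dominant	secondary	co_occurrence	dominant_only	secondary_only	intact	or_printed	p_printed	q_printed	direction
ASXL1	ASXL1	1	136	211	1461	0.1	6.14E-07	2.77E-05	ME
ASXL1	SRSF2	16	121	72	1600	2.9	6.20E-04	8.15E-03	CO
BCOR	ETV6	8	40	27	1734	12.8	1.85E-06	6.99E-05	CO
BCOR	RUNX1	10	38	99	1662	4.4	3.93E-04	5.72E-03	CO
BCOR	U2AF1	6	42	26	1735	9.5	1.36E-04	2.63E-03	CO
CBL	ASXL1	10	15	202	1582	5.2	2.64E-04	4.38E-03	CO
EZH2	ASXL1	25	38	187	1559	5.5	5.99E-09	4.73E-07	CO
EZH2	EZH2	8	55	43	1703	5.7	2.69E-04	4.39E-03	CO
EZH2	FLT3	5	58	13	1733	11.4	2.64E-04	4.38E-03	CO
EZH2	RUNX1	23	40	86	1660	11.1	1.15E-13	2.17E-11	CO
EZH2	STAG2	10	53	74	1672	4.3	4.61E-04	6.41E-03	CO
EZH2	TET2	22	41	236	1510	3.4	2.26E-05	5.38E-04	CO
IDH2	ASXL1	17	33	195	1564	4.1	2.26E-05	5.38E-04	CO
IDH2	SRSF2	16	34	72	1687	11.0	3.24E-10	3.41E-08	CO
IDH2	STAG2	11	39	73	1686	6.5	9.52E-06	2.65E-04	CO
IDH2	TET2	0	50	258	1501	Infinity	6.99E-04	8.70E-03	ME
RUNX1	ASXL1	22	51	190	1546	3.5	1.25E-05	3.20E-04	CO
RUNX1	BCOR	8	65	37	1699	5.6	3.09E-04	4.88E-03	CO
RUNX1	IDH2	8	65	15	1721	14.1	1.44E-06	5.93E-05	CO
RUNX1	STAG2	17	56	67	1669	7.5	9.50E-09	6.42E-07	CO
SF3B1	ASXL1	20	354	192	1243	0.4	5.26E-06	1.72E-04	ME
SF3B1	DNMT3A	23	351	35	1400	2.6	7.71E-04	9.35E-03	CO
SF3B1	JAK2	29	345	24	1411	4.9	3.05E-08	1.92E-06	CO
SF3B1	NRAS	1	373	46	1389	0.1	3.66E-04	5.52E-03	ME
SF3B1	SRSF2	3	371	85	1350	0.1	4.56E-06	1.54E-04	ME
SRSF2	ASXL1	48	114	164	1483	3.8	6.05E-11	7.15E-09	CO
SRSF2	CBL	14	148	47	1600	3.2	6.53E-04	8.41E-03	CO
SRSF2	SRSF2	0	162	88	1559	Infinity	3.73E-04	5.52E-03	ME
SRSF2	STAG2	21	141	63	1584	3.7	6.40E-06	1.95E-04	CO
SRSF2	TET2	44	118	214	1433	2.5	5.46E-06	1.72E-04	CO
STAG2	ASXL1	19	41	193	1556	3.7	2.33E-05	5.38E-04	CO
TET2	TET2	125	222	133	1329	5.6	1.00E-31	9.47E-29	CO
TET2	ZRSR2	26	321	23	1439	5.1	7.51E-08	4.44E-06	CO
TP53	ASXL1	2	107	210	1490	0.1	1.75E-04	3.18E-03	ME
TP53	TP53	19	90	17	1683	20.8	5.12E-15	1.21E-12	CO
U2AF1	ASXL1	32	75	180	1522	3.6	1.27E-07	7.06E-06	CO
ZRSR2	TET2	23	49	235	1502	3.0	8.69E-05	1.79E-03	CO
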