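proteinId	tmhmm	NW305 -Fe_a	NW186 -Fe_a	log2FC	FDR	NW186 +Fe_a	NW186 +Fe_c	log2FC	FDR	NW305 -Fe_a	NW305 ++Fe_a	log2FC	FDR
1165828	12	14.61 ± 0.99	139.89 ± 22.45	3.42	0.00	34.03 ± 1.52	350.11 ± 111.78	3.30	0.00	14.61 ± 0.99	4.73 ± 0.46	−1.75	0.00
1186388	14	22.65 ± 1.00	64.92 ± 2.47	1.67	0.00	70.22 ± 5.08	250.45 ± 19.01	1.78	0.00	22.65 ± 1.00	6.90 ± 0.82	−1.88	0.00
212337	4	52.79 ± 7.20	123.91 ± 0.68	1.44	0.00	34.70 ± 1.91	116.80 ± 16.22	1.66	0.00	52.79 ± 7.20	41.65 ± 2.17	−0.44	0.48
1187835	12	24.73 ± 0.33	53.79 ± 6.51	1.26	0.00	87.03 ± 8.32	109.85 ± 46.96	0.27	0.89	24.73 ± 0.33	9.74 ± 1.07	−1.51	0.00
1155853	5	62.05 ± 1.00	132.17 ± 18.17	1.23	0.00	61.63 ± 2.29	108.63 ± 3.11	0.77	0.05	62.05 ± 1.00	61.59 ± 6.45	−0.16	0.85
1105147	14	202.52 ± 38.35	407.77 ± 8.54	1.15	0.01	34.77 ± 2.66	377.25 ± 25.34	3.42	0.00	202.52 ± 38.35	2.88 ± 0.05	−6.32	0.00
1120210	7	76.98 ± 1.19	110.49 ± 2.48	0.66	0.28	55.93 ± 0.80	65.12 ± 9.50	0.16	0.93	76.98 ± 1.19	73.30 ± 2.75	−0.24	0.75
1178251	5	1.77 ± 0.11	2.25 ± 0.34	0.62	0.55	1.34 ± 0.12	1.07 ± 0.15	−0.37	0.76	1.77 ± 0.11	2.69 ± 0.11	0.51	0.44
1137850	0	88.34 ± 5.03	118.68 ± 1.26	0.58	0.43	51.68 ± 4.67	219.35 ± 35.84	2.03	0.00	88.34 ± 5.03	26.41 ± 1.27	−1.91	0.00
1126790	1	37.23 ± 1.28	47.80 ± 1.56	0.53	0.52	54.66 ± 1.84	26.97 ± 3.30	−1.07	0.00	37.23 ± 1.28	55.51 ± 1.16	0.44	0.46
1141368	0	283.79 ± 3.09	367.47 ± 40.06	0.52	0.55	350.33 ± 11.21	420.75 ± 115.76	0.20	0.91	283.79 ± 3.09	254.87 ± 14.52	−0.33	0.63
1164596	4	196.19 ± 1.18	249.19 ± 20.70	0.50	0.59	75.44 ± 5.94	113.96 ± 9.73	0.53	0.41	196.19 ± 1.18	148.70 ± 9.82	−0.56	0.28
1146389	1	108.54 ± 4.88	138.31 ± 19.36	0.50	0.59	116.63 ± 2.51	186.06 ± 4.83	0.63	0.21	108.54 ± 4.88	108.48 ± 6.72	−0.15	0.86
1082759	1	87.33 ± 5.64	99.05 ± 0.51	0.34	0.81	64.14 ± 0.23	68.81 ± 11.91	0.05	0.98	87.33 ± 5.64	58.61 ± 6.89	−0.72	0.11
1125366	4	132.02 ± 17.77	146.93 ± 8.62	0.31	0.84	37.41 ± 1.48	109.57 ± 0.12	1.50	0.00	132.02 ± 17.77	75.85 ± 6.71	−0.92	0.02
1019516	2	144.19 ± 12.89	161.84 ± 26.21	0.31	0.85	192.89 ± 0.71	218.35 ± 9.92	0.12	0.95	144.19 ± 12.89	135.13 ± 13.09	−0.23	0.76
1104917	0	188.49 ± 34.04	207.27 ± 13.58	0.30	0.86	273.96 ± 4.26	290.30 ± 37.78	0.02	0.99	188.49 ± 34.04	106.56 ± 2.73	−0.97	0.02
1121445	11	57.61 ± 1.74	63.01 ± 2.36	0.28	0.87	72.90 ± 0.47	104.82 ± 12.52	0.46	0.54	57.61 ± 1.74	37.15 ± 4.55	−0.80	0.05
40744	3	34.08 ± 1.51	37.29 ± 3.56	0.27	0.88	132.37 ± 11.64	40.86 ± 6.76	−1.76	0.00	34.08 ± 1.51	82.38 ± 0.63	1.11	0.00
1178940	0	194.27 ± 13.70	213.06 ± 21.16	0.27	0.88	664.99 ± 5.60	612.42 ± 39.79	−0.16	0.93	194.27 ± 13.70	393.00 ± 37.13	0.85	0.05
1113466	2	338.24 ± 10.36	365.49 ± 48.70	0.24	0.91	455.53 ± 13.84	401.65 ± 53.28	−0.24	0.88	338.24 ± 10.36	423.61 ± 7.25	0.12	0.89
1156700	5	98.40 ± 3.12	101.76 ± 3.19	0.20	0.93	434.89 ± 16.18	257.81 ± 44.29	−0.80	0.07	98.40 ± 3.12	225.43 ± 20.94	1.03	0.00
1165578	12	110.33 ± 11.86	112.62 ± 0.55	0.19	0.94	107.22 ± 2.38	158.33 ± 12.11	0.51	0.44	110.33 ± 11.86	53.59 ± 0.79	−1.20	0.00
1120082	5	146.10 ± 6.70	142.51 ± 2.09	0.13	0.96	149.21 ± 1.74	172.49 ± 17.22	0.16	0.93	146.10 ± 6.70	142.19 ± 0.58	−0.18	0.82
1121621	12	509.21 ± 69.19	497.06 ± 41.68	0.13	0.96	287.69 ± 2.48	366.00 ± 34.79	0.29	0.82	509.21 ± 69.19	503.96 ± 74.66	−0.18	0.83
1147788	5	82.76 ± 8.14	76.08 ± 3.74	0.06	0.99	93.44 ± 3.39	136.89 ± 28.41	0.51	0.50	82.76 ± 8.14	72.84 ± 1.82	−0.34	0.62
1092996	4	108.82 ± 13.42	100.63 ± 3.30	0.04	0.99	103.47 ± 3.68	121.62 ± 8.56	0.18	0.92	108.82 ± 13.42	92.85 ± 0.01	−0.39	0.54
1163349	0	29.36 ± 1.78	26.80 ± 1.03	0.02	0.99	35.36 ± 1.44	32.46 ± 1.63	−0.17	0.93	29.36 ± 1.78	27.31 ± 0.94	−0.27	0.71
1141295	2	197.00 ± 8.52	180.50 ± 1.00	0.01	1.00	112.86 ± 4.46	136.16 ± 7.77	0.20	0.91	197.00 ± 8.52	150.75 ± 3.28	−0.55	0.29
1103501	14	140.87 ± 5.80	128.08 ± 13.18	0.01	1.00	96.46 ± 6.34	206.50 ± 33.35	1.05	0.00	140.87 ± 5.80	3.30 ± 0.06	−5.56	0.00
1172271	1	134.47 ± 5.07	121.28 ± 1.70	0.00	1.00	66.79 ± 2.94	82.65 ± 12.41	0.24	0.87	134.47 ± 5.07	107.55 ± 1.94	−0.47	0.42
1219631	0	1.92 ± 0.37	1.56 ± 0.08	−0.01	1.00	4.76 ± 0.47	5.85 ± 1.00	0.28	0.85	1.92 ± 0.37	1.64 ± 0.37	−0.30	0.72
177364	1	2.82 ± 0.18	2.61 ± 0.00	−0.03	0.99	1.88 ± 0.07	1.87 ± 0.32	0.01	1.00	2.82 ± 0.18	1.46 ± 0.05	−1.04	0.03
1137953	2	40.68 ± 3.74	34.00 ± 3.57	−0.11	0.97	141.12 ± 2.32	63.58 ± 6.84	−1.21	0.00	40.68 ± 3.74	85.18 ± 6.98	0.92	0.02
1117050	3	40.36 ± 1.55	32.08 ± 4.00	−0.16	0.95	46.35 ± 3.98	53.35 ± 4.46	0.15	0.94	40.36 ± 1.55	21.28 ± 0.77	−1.07	0.00
1141371	0	1571.19 ± 246.87	1249.67 ± 120.07	−0.17	0.95	551.49 ± 6.68	518.11 ± 5.14	−0.15	0.94	1571.19 ± 246.87	740.57 ± 40.61	−1.22	0.00
1147568	4	7482.49 ± 509.41	5782.62 ± 105.11	−0.22	0.92	3164.92 ± 14.66	3994.04 ± 231.82	0.28	0.84	7482.49 ± 509.41	6622.43 ± 20.86	−0.36	0.60
1181871	12	49.66 ± 1.89	36.63 ± 0.94	−0.29	0.87	37.12 ± 0.83	30.34 ± 6.81	−0.36	0.74	49.66 ± 1.89	35.43 ± 0.48	−0.65	0.16
1209512	0	50.80 ± 5.25	36.89 ± 3.37	−0.30	0.85	89.37 ± 2.45	60.30 ± 0.80	−0.61	0.25	50.80 ± 5.25	87.27 ± 4.03	0.62	0.20
1011311	0	55.14 ± 2.22	38.64 ± 6.57	−0.36	0.79	119.93 ± 7.34	98.35 ± 0.78	−0.34	0.76	55.14 ± 2.22	88.47 ± 3.26	0.55	0.28
1168387	0	60.92 ± 2.05	40.64 ± 0.63	−0.45	0.66	91.23 ± 0.81	80.83 ± 10.18	−0.22	0.89	60.92 ± 2.05	59.55 ± 5.52	−0.22	0.78
1141800	1	43.05 ± 0.75	25.30 ± 1.81	−0.61	0.36	120.51 ± 4.34	73.38 ± 12.23	−0.79	0.07	43.05 ± 0.75	59.09 ± 1.45	0.35	0.60
1169809	12	113.09 ± 7.38	58.75 ± 7.85	−0.79	0.14	195.35 ± 3.82	323.04 ± 63.23	0.66	0.24	113.09 ± 7.38	140.31 ± 24.63	0.18	0.83
1164227	2	43.66 ± 2.41	19.30 ± 1.11	−1.01	0.01	124.93 ± 0.50	30.60 ± 1.03	−2.08	0.00	43.66 ± 2.41	100.11 ± 12.83	1.04	0.00
1148364	0	66.99 ± 4.34	29.59 ± 0.47	−1.02	0.01	19.77 ± 1.34	31.72 ± 6.23	0.60	0.35	66.99 ± 4.34	21.58 ± 1.63	−1.75	0.00
1222809	0	172.06 ± 39.87	70.73 ± 9.77	−1.10	0.05	52.51 ± 0.89	74.55 ± 15.51	0.44	0.61	172.06 ± 39.87	14.50 ± 1.37	−3.74	0.00
1115499	0	41.79 ± 0.54	14.21 ± 0.30	−1.40	0.00	25.87 ± 1.86	19.65 ± 1.58	−0.44	0.59	41.79 ± 0.54	30.57 ± 3.99	−0.60	0.24
1146086	1	73.65 ± 8.51	23.91 ± 0.59	−1.47	0.00	61.61 ± 1.55	63.36 ± 9.68	0.00	1.00	73.65 ± 8.51	26.66 ± 0.81	−1.62	0.00
37369	0	0.03 ± 0.02	− ± −	#N/A	#N/A	0.03 ± 0.02	0.02 ± 0.01	#N/A	#N/A	0.03 ± 0.02	− ± −	#N/A	#N/A
1178960	0	0.23 ± 0.05	0.46 ± 0.02	#N/A	#N/A	0.71 ± 0.07	0.50 ± 0.00	#N/A	#N/A	0.23 ± 0.05	0.73 ± 0.11	#N/A	#N/A
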