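Species	Panel	Size	A	G	T	C	AT	ATskew	GCskew
D. nerii	Whole genome	15247	40.81	7.58	39.48	12.13	80.29	0.017	-0.231
M. sexta	Whole genome	15516	40.67	7.46	41.11	10.76	81.79	-0.005	-0.181
S. morio	Whole genome	15299	40.64	7.58	40.53	11.23	81.17	0.001	-0.194
B. mandarina	Whole genome	15682	43.11	7.40	38.48	11.01	81.59	0.057	-0.196
A. pernyi	Whole genome	15566	39.22	7.77	40.94	12.07	80.16	-0.021	-0.216
L. dispar	Whole genome	15569	40.58	7.57	39.30	12.55	79.88	0.016	-0.248
L. melli	Whole genome	15418	39.38	8.72	39.29	13.06	78.67	0.001	-0.199
H. cunea	Whole genome	15481	40.58	7.55	39.81	12.06	80.39	0.010	-0.230
A. formosae	Whole genome	15463	38.67	7.53	40.83	12.98	79.49	-0.027	-0.266
G. argentata	Whole genome	15337	39.64	7.56	42.05	10.75	81.69	0.030	-0.174
C. pomonella	Whole genome	15253	39.92	7.88	40.21	11.99	80.13	-0.004	-0.207
P. atrilineata	Whole genome	15499	40.78	7.67	40.24	11.31	81.02	0.007	-0.192
A. ilia	Whole genome	15242	39.77	7.75	40.68	11.80	80.45	-0.011	-0.207
G. dimorpha	Whole genome	15831	39.99	7.77	40.85	11.39	80.84	-0.011	-0.189
H. vitta	Whole genome	15282	39.58	7.81	40.34	12.27	79.92	-0.010	-0.222
C. suppressalis	Whole genome	15395	40.64	7.39	40.03	11.94	80.67	0.007	-0.235
A. ipsilon	Whole genome	15377	40.38	7.71	40.87	11.04	81.25	-0.006	-0.178
D. nerii	PCG	11208	40.52	8.32	38.15	13.00	78.68	0.030	-0.220
M. sexta	PCG	11185	40.41	8.23	39.88	11.48	80.30	0.007	-0.165
S. morio	PCG	11179	40.28	8.27	39.56	11.89	79.84	0.009	-0.180
B. mandarina	PCG	11196	42.83	8.26	37.04	11.87	79.87	0.072	-0.179
A. pernyi	PCG	11204	39.22	7.77	40.94	12.07	80.16	-0.021	-0.216
L. dispar	PCG	11227	39.67	8.44	38.16	13.73	77.83	0.019	-0.239
L. melli	PCG	11120	38.47	9.17	38.17	14.19	76.64	0.004	-0.215
H. cunea	PCG	11198	39.98	8.35	38.61	13.06	78.59	0.017	-0.220
A. formosae	PCG	11217	38.18	8.28	39.62	13.92	77.80	-0.019	-0.254
G. argentata	PCG	10303	38.10	8.61	41.88	11.41	79.98	-0.047	-0.140
C. pomonella	PCG	11199	39.55	8.69	39.00	12.76	78.55	0.007	-0.190
P. atrilineata	PCG	11203	40.23	8.59	38.87	12.31	79.10	0.017	-0.178
A. ilia	PCG	11148	39.41	8.41	39.49	12.69	78.89	-0.001	-0.203
G. dimorpha	PCG	11232	39.51	8.81	39.18	12.49	78.69	0.004	-0.173
H. vitta	PCG	11202	38.76	8.61	39.43	13.20	78.19	-0.009	-0.210
C. suppressalis	PCG	11230	40.42	8.16	38.48	12.95	78.90	0.025	-0.227
A. ipsilon	PCG	11226	39.69	8.44	40.14	11.72	79.83	-0.006	-0.163
D. nerii	tRNA	1586	41.74	7.38	40.79	10.09	82.53	0.012	-0.155
M. sexta	tRNA	1554	40.99	7.92	41.06	10.04	82.05	-0.001	-0.118
S. morio	tRNA	1462	40.63	8.21	40.97	10.19	81.60	-0.004	-0.107
B. mandarina	tRNA	1472	41.78	7.81	39.95	10.46	81.73	0.022	-0.145
A. pernyi	tRNA	1459	39.22	7.77	40.94	12.07	80.16	-0.021	-0.217
L. dispar	tRNA	1459	41.60	7.95	39.48	10.97	81.08	0.026	-0.160
L. melli	tRNA	1486	40.58	8.55	40.24	10.63	80.82	0.004	-0.109
H. cunea	tRNA	1463	41.83	7.86	39.99	10.32	81.82	0.022	-0.135
A. formosae	tRNA	1457	40.43	7.96	40.36	11.26	80.78	0.001	-0.172
G. argentata	tRNA	1468	41.35	8.24	40.19	10.22	81.54	0.014	-0.107
C. pomonella	tRNA	1464	41.19	7.92	40.23	10.66	81.42	0.012	-0.147
P. atrilineata	tRNA	1476	41.4	8.2	40.04	10.37	81.44	0.017	-0.117
A. ilia	tRNA	1433	40.61	8.30	40.96	10.12	81.58	-0.004	-0.099
G. dimorpha	tRNA	1451	41.01	8.06	40.52	10.41	81.53	0.006	-0.127
H. vitta	tRNA	1456	41.41	8.04	39.84	10.71	81.25	0.019	-0.142
C. suppressalis	tRNA	1482	40.89	7.89	40.89	10.32	81.78	0.000	-0.133
A. ipsilon	tRNA	1465	41.23	8.12	40.48	10.17	81.71	0.009	-0.112
D. nerii	rRNA	2117	42.14	4.87	42.61	10.39	84.74	-0.006	-0.362
M. sexta	rRNA	2168	41.37	4.84	44.05	9.73	85.42	-0.031	-0.336
S. morio	rRNA	2152	41.73	4.83	43.08	10.36	84.8	-0.016	-0.364
B. mandarina	rRNA	2134	43.86	4.78	41.05	10.31	84.91	0.033	-0.366
A. pernyi	rRNA	2144	39.22	7.77	40.94	12.07	80.16	-0.021	-0.217
L. dispar	rRNA	2150	42.79	4.79	41.81	10.60	84.60	0.012	-0.377
L. melli	rRNA	2233	42.23	4.93	41.96	10.88	84.19	0.003	-0.376
H. cunea	rRNA	2234	42.08	4.92	42.75	10.25	84.83	-0.008	-0.351
A. formosae	rRNA	2163	38.93	4.72	44.85	11.51	83.77	-0.071	-0.418
G. argentata	rRNA	2165	40.6	4.76	45.13	9.52	85.73	-0.053	-0.333
C. pomonella	rRNA	2147	40.48	5.03	43.92	10.57	84.4	-0.041	-0.355
P. atrilineata	rRNA	2203	42.85	4.58	43.08	9.49	85.93	-0.003	-0.349
A. ilia	rRNA	2109	40.11	4.98	44.86	10.05	84.97	-0.056	-0.337
G. dimorpha	rRNA	2181	41.13	4.95	43.83	10.09	84.96	-0.032	-0.342
H. vitta	rRNA	2194	41.43	4.88	43.25	10.44	84.69	-0.021	-0.363
C. suppressalis	rRNA	2171	41.27	4.97	43.67	10.09	84.94	-0.028	-0.340
A. ipsilon	rRNA	2162	41.58	5	43.57	9.85	85.15	-0.023	-0.327
D. nerii	A+T-rich region	351	41.60	1.42	53.56	3.42	95.16	-0.126	-0.413
M. sexta	A+T-rich region	324	45.06	1.54	50.31	3.09	95.37	-0.005	-0.335
S. morio	A+T-rich region	316	44.3	2.53	48.42	4.75	92.72	-0.044	-0.305
B. mandarina	A+T-rich region	484	46.49	2.69	47.93	2.89	94.42	-0.015	-0.036
A. pernyi	A+T-rich region	552	39.22	7.77	40.94	12.07	80.16	-0.021	-0.216
L. dispar	A+T-rich region	435	40.58	7.57	39.30	12.55	79.88	0.016	-0.248
L. melli	A+T-rich region	338	43.2	1.48	51.18	4.14	94.38	-0.085	-0.473
H. cunea	A+T-rich region	357	45.66	1.12	49.3	3.92	94.96	-0.038	-0.556
A. formosae	A+T-rich region	482	42.95	2.9	49.79	4.36	92.74	-0.074	-0.201
G. argentata	A+T-rich region	340	43.24	1.47	52.06	3.24	95.29	-0.093	-0.376
C. pomonella	A+T-rich region	351	43.3	1.14	52.42	3.13	95.73	-0.095	-0.466
P. atrilineata	A+T-rich region	457	40.7	0.66	57.55	1.09	98.25	-0.172	-0.246
A. ilia	A+T-rich region	403	42.93	3.23	49.63	4.22	92.56	-0.072	-0.133
G. dimorpha	A+T-rich region	848	41.63	1.30	54.83	2.24	96.46	-0.137	-0.266
C. suppressalis	A+T-rich region	348	42.24	0.29	53.16	4.31	95.4	-0.114	-0.874
A. ipsilon	A+T-rich region	332	46.08	1.51	48.8	3.61	94.88	-0.029	-0.41
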