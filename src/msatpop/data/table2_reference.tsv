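# Transcription of published per-locus diversity and F-statistics values
# (whole-sample table) for the Togolese indigenous guinea fowl survey.
# These are transcribed reference numbers, not outputs of this package.
locus	Na	AR	Ae	Ho	He	PIC	FIT	FST	FIS
GF43	4	2.8	2.14	0.439	0.489	0.487	0.202	0.042	0.167
GUJ0001	3	1.9	1.34	0.203	0.266	0.235	0.184	0.027	0.161
GUJ0059	7	3.9	3.70	0.390	0.662	0.696	0.347	0.037	0.322
GUJ0066	25	5.3	6.14	0.540	0.811	0.825	0.323	0.009	0.317
GF13	7	3.6	3.40	0.502	0.655	0.663	0.258	0.026	0.238
GF5	2	2.0	1.88	0.447	0.452	0.358	0.059	0.000	0.070
GUJ0084	2	2.0	1.87	0.470	0.447	0.356	-0.014	0.001	-0.015
GF30	3	2.1	1.97	0.308	0.454	0.386	0.329	0.022	0.314
GF75	4	2.6	2.27	0.472	0.576	0.474	0.205	0.000	0.223
GF168	4	3.2	3.17	0.663	0.703	0.621	0.064	0.000	0.088
GF12	8	4.0	3.56	0.732	0.727	0.691	0.037	0.000	0.041
GUJ0013	4	3.1	3.15	0.663	0.702	0.618	0.062	0.000	0.084
GF37	7	3.6	3.61	0.816	0.740	0.673	-0.122	0.000	-0.106
GUJ0086	5	3.0	2.92	0.548	0.651	0.589	0.227	0.000	0.229
MCW0222	5	3.2	3.23	0.678	0.707	0.630	0.042	0.000	0.064
GF69	7	3.2	2.84	0.502	0.644	0.592	0.277	0.015	0.266
GF74	4	2.8	2.38	0.366	0.538	0.515	0.300	0.000	0.300
MCW0069	7	3.3	2.92	0.487	0.646	0.599	0.301	0.031	0.279
Average	6.00	3.08	2.92	0.512	0.604	0.556	0.171	0.012	0.169
SD	5.10	0.85	1.06	0.154	0.137	0.149	0.139	0.015	0.128
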