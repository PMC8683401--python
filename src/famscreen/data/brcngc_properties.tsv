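# Physico-chemical properties of the 29 BrCNGC proteins, transcribed from the
# published protein-properties table (ProtParam-derived values).
# mw_kda = molecular weight (kDa); pi = theoretical isoelectric point;
# instability = instability index; aliphatic = aliphatic index;
# gravy = grand average of hydropathicity; avg_residue_weight in g/mol;
# charge = net charge as printed (pH convention unstated in the source);
# localization = predicted subcellular localization (external predictor,
# carried as annotation only).
protein	length_aa	mw_kda	pi	instability	aliphatic	gravy	avg_residue_weight	charge	localization
BrCNGC1	647	74.76	9.52	40.4	100.8	-0.021	115.555	38.0	PM
BrCNGC2	666	75.66	8.34	41.0	93.11	-0.078	113.604	10.0	PM
BrCNGC3	702	81.03	9.14	42.2	88.89	-0.15	115.430	25.0	PM
BrCNGC4	556	64.27	8.91	41.1	92.91	-0.135	115.594	19.0	PM
BrCNGC5	705	81.34	9.3	48.3	91.3	-0.212	115.381	25.0	PM
BrCNGC6	758	88.06	9.63	50.0	83.61	-0.223	116.172	43.0	PM
BrCNGC7	739	85.76	9.25	56.4	90	-0.131	116.049	28.0	PM
BrCNGC8	712	81.81	9.1	51.8	87.4	-0.242	114.900	19.0	PM
BrCNGC9	749	85.58	9.11	50.2	89.47	-0.101	114.271	24.5	PM
BrCNGC10	746	85.43	9.5	51.8	89.44	-0.188	114.523	37.5	PM
BrCNGC11	737	84.65	9.44	50.6	92.24	-0.181	114.863	31.0	PM
BrCNGC12	712	81.03	9.34	46.5	93.3	-0.134	113.813	26.0	PM
BrCNGC13	684	79.43	9.68	46.4	91.51	-0.102	116.127	38.0	PM
BrCNGC14	714	81.34	8.51	45.0	85.78	-0.141	113.926	13.0	PM
BrCNGC15	706	81.52	8.58	52.6	86.08	-0.247	115.469	15.0	PM
BrCNGC16	728	84.28	8.95	46.5	90.41	-0.212	115.768	18.5	PM
BrCNGC17	733	84.49	9.2	48.2	93.11	-0.131	115.271	24.0	PM
BrCNGC18	728	83.82	9.06	46.9	92.94	-0.103	115.139	21.5	PM
BrCNGC19	695	80.35	8.32	52.5	90.14	-0.186	115.610	11.5	PM
BrCNGC20	698	80.57	8.52	54.3	91.16	-0.174	115.431	13.0	PM
BrCNGC21	719	82.07	9.53	56.8	94.21	0.008	114.147	36.0	PM
BrCNGC22	654	74.65	8.98	41.2	96.07	-0.049	114.138	19.0	PM
BrCNGC23	758	85.32	8.73	45.5	96.45	0.042	112.566	16.5	PM
BrCNGC24	670	75.62	9.58	44.1	90.81	-0.117	112.866	31.0	PM
BrCNGC25	743	85.29	9.61	52.9	89.22	-0.134	114.803	35.5	PM
BrCNGC26	748	86.20	9.26	51.9	88.76	-0.197	115.243	22.5	PM
BrCNGC27	680	77.60	8.94	50.7	89.46	-0.149	114.121	15.0	PM
BrCNGC28	760	86.24	9.55	48.0	91.37	-0.063	113.481	32.5	PM
BrCNGC29	786	90.34	9.71	48.3	89.66	-0.186	114.942	35.0	PM
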