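metabolite	kegg_id	vip_mean	vip_ci_lower	vip_ci_upper	log2_fc	p_value	fdr	cv_percent	validation_level	age_corrected
Caffeine	C07481	1.84	1.80	1.88	-1.97	4.3e-3	0.033	24.4	2	1
Citrulline	C00327	1.83	1.76	1.90	0.55	5.4e-3	0.033	14.2	1	0
1-Methyladenosine	C02494	1.80	1.77	1.84	0.40	1.9e-3	0.033	11.5	2	0
3-Methoxytyramine	C05587	1.79	1.72	1.85	-1.16	0.012	0.049	26.7	1	1
4-Acetamidobutanoate	C02946	1.69	1.64	1.74	0.43	6.1e-3	0.033	9.2	2	0
N-Acetylserotonin	C00978	1.65	1.57	1.73	0.59	6.2e-3	0.033	16.8	1	0
O-Succinyl-homoserine	C01118	1.64	1.60	1.69	0.28	4.7e-3	0.033	14.3	1	0
N6- (delta2-isopentenyl)-adenine [M + H]	C04083	1.64	1.59	1.69	0.36	9.8e-3	0.045	5.4	1	0
Trigonelline	C01004	1.59	1.51	1.66	0.20	0.021	0.067	11.3	1	0
5-Hydroxytryptophan	C00643	1.47	1.42	1.52	0.57	0.016	0.057	15.8	1	0
Kynurenate	C01717	1.37	1.32	1.43	0.60	0.039	0.113	9.1	1	0
N-Acetylneuraminate	C00270	1.37	1.29	1.45	-0.27	0.062	0.117	7.0	2	0
N6- (delta2-isopentenyl)-adenine [M - H]	C04083	1.32	1.26	1.38	0.29	0.075	0.126	8.3	1	0
N-Acetylphenylalanine [M + H]	C03519	1.32	1.26	1.37	0.23	0.054	0.116	6.9	1	1
Deoxyuridine	C00526	1.31	1.24	1.37	-0.37	0.050	0.114	13.8	1	0
Homogentisate	C00544	1.28	1.21	1.36	0.21	0.050	0.114	18.6	1	0
5-Hydroxyindoleacetate	C05635	1.26	1.20	1.32	-0.38	0.101	0.135	11.7	1	0
Pipecolate	C00408	1.24	1.16	1.31	0.37	0.042	0.113	7.5	1	0
N-Acetylleucine	C02710	1.19	1.13	1.26	0.15	0.145	0.178	5.8	1	0
Indole-3-acetate	C00954	1.19	1.13	1.24	0.54	0.066	0.117	12.2	2	0
Uridine	C00299	1.17	1.10	1.24	0.19	0.087	0.132	7.4	2	0
Indoxyl sulfate	C08481	1.17	1.09	1.25	-0.35	0.244	0.252	24.0	2	1
N-Acetyltryptophan	C03137	1.12	1.06	1.18	0.35	0.058	0.116	4.3	1	1
Deoxycarnitine	C01181	1.10	0.99	1.20	-0.27	0.214	0.228	6.8	1	0
Xanthosine	C01762	1.09	1.02	1.16	0.26	0.096	0.134	8.8	1	0
Phenylacetate	C07086	1.08	1.00	1.16	0.18	0.202	0.222	8.7	2	0
Ketoleucine	C00233	1.07	1.02	1.11	0.07	0.083	0.132	7.6	2	0
Carnitine	C00318	1.07	0.97	1.16	-0.18	0.166	0.189	5.8	2	0
Guanosine	C00387	1.06	0.99	1.13	0.13	0.162	0.189	7.8	2	0
N-Acetylphenylalanine [M - H]	C03519	1.03	0.96	1.11	0.13	0.260	0.260	9.3	1	1
4-Pyridoxate	C00847	1.02	0.97	1.06	0.48	0.094	0.134	12.2	1	0
4-Hydroxybenzoate	C00156	1.02	0.94	1.09	0.17	0.113	0.145	11.5	1	0
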