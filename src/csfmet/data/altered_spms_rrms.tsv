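metabolite	kegg_id	vip_mean	vip_ci_lower	vip_ci_upper	log2_fc	p_value	fdr	cv_percent	validation_level	age_corrected
Thymine	C00178	2.01	1.95	2.07	0.49	5.0e-5	1.8e-3	7.9	1	0
Glutarylcarnitine		1.84	1.79	1.90	0.48	2.4e-4	4.4e-3	9.3	2	0
Biliverdin	C00500	1.78	1.72	1.83	0.90	1.6e-3	0.011	24.7	1	0
Pipecolate	C00408	1.77	1.70	1.83	0.56	1.9e-3	0.011	7.5	1	0
Uridine	C00299	1.76	1.70	1.82	0.33	9.4e-4	0.011	7.4	2	0
4-Acetamidobutanoate	C02946	1.72	1.67	1.78	0.40	2.1e-3	0.011	9.2	2	0
Deoxyuridine	C00526	1.67	1.62	1.72	-0.50	1.4e-3	0.011	13.8	1	0
Ethylmalonate		1.63	1.56	1.70	0.46	9.7e-3	0.030	7.1	2	0
Valine	C00183	1.61	1.56	1.66	0.25	4.2e-3	0.020	4.5	2	0
O-Succinyl-homoserine	C01118	1.57	1.52	1.62	0.24	6.4e-3	0.021	14.3	1	0
Methionine	C00073	1.56	1.51	1.62	0.32	6.0e-3	0.021	3.4	2	0
Glutamine	C00064	1.51	1.46	1.56	0.31	6.3e-3	0.021	22.3	2	0
3-Methoxytyrosine [M + H]		1.38	1.31	1.45	0.80	0.075	0.088	6.8	2	0
Phenylacetate	C07086	1.38	1.32	1.43	0.26	0.031	0.052	8.7	2	0
N-Acetylleucine	C02710	1.37	1.33	1.42	0.24	0.016	0.038	5.8	1	0
Phenylalanine	C00079	1.35	1.30	1.39	0.23	0.021	0.043	4.6	2	0
1-Methyladenosine	C02494	1.34	1.28	1.39	0.26	0.017	0.040	11.5	2	0
Urate	C00366	1.25	1.20	1.31	0.44	0.013	0.037	8.6	2	0
Caffeine	C07481	1.25	1.18	1.32	-1.12	0.078	0.088	24.4	2	1
Ketoleucine	C00233	1.25	1.19	1.31	0.09	0.034	0.052	7.6	2	0
Tyrosine	C00082	1.25	1.21	1.29	0.25	0.034	0.052	5.2	2	0
N6-(delta2-isopentenyl)-adenine	C04083	1.23	1.17	1.29	0.29	0.028	0.049	5.4	1	0
N-Acetylphenylalanine [M + H]	C03519	1.23	1.18	1.27	0.21	0.044	0.061	6.9	1	1
3-Methoxytyramine	C05587	1.20	1.14	1.26	-0.75	0.038	0.054	26.7	1	1
Cyclic AMP	C00575	1.20	1.10	1.31	0.28	0.020	0.043	12.0	1	0
N-Acetylserotonin	C00978	1.20	1.15	1.25	0.44	0.023	0.045	16.8	1	0
3,4-Dihydroxyphenylglycol	C05576	1.18	1.13	1.24	0.28	0.015	0.038	15.9	1	0
Guanosine	C00387	1.17	1.10	1.25	0.16	0.035	0.052	7.8	2	0
Kynurenine	C00328	1.12	1.06	1.18	0.37	0.048	0.063	7.9	2	0
Isoleucine/Leucine	C00407	1.10	1.05	1.15	0.21	0.078	0.088	6.5	2	0
Kynurenate	C01717	1.09	1.02	1.16	0.43	0.050	0.064	9.1	1	0
5-Hydroxytryptophan	C00643	1.09	1.02	1.15	0.45	0.055	0.068	15.8	1	0
3-Methoxytyrosine [M - H]		1.08	1.05	1.12	0.65	0.146	0.150	12.0	1	0
4-Guanidinobutanoate	C01035	1.06	1.01	1.12	-0.24	0.028	0.049	7.9	1	0
5-Hydroxyindoleacetate	C05635	1.06	0.99	1.12	-0.35	0.083	0.091	11.7	1	0
Trigonelline	C01004	1.05	0.97	1.12	0.09	0.157	0.157	11.3	1	0
3-Hydroxymethylglutarate	C03761	1.01	0.94	1.08	-0.25	0.107	0.113	13.3	1	0
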