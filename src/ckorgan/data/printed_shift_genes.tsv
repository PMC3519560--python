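probe_id	abb	r_root_BA1080	r_shoot_CKX1	r_base	q_cytokinin	q_organ	q_interaction	agi	localization	description
CATMA2a26583	40	2.71	0.09	0.04	5.78e-07	3.27e-11	1.12e-06	AT2G28190	a,P	superoxide dismutase (Cu-Zn) (SODCP)
CATMA5a16150	35	2.8	0.09	0.03	1.83e-06	5.98e-18	2.95e-05	AT5G17870	P	plastid-specific ribosomal protein-related
CATMA3a44603	29	2.71	0.12	0.0	0.00468	2.58e-21	5.67e-05	AT3G51600	w	nonspecific lipid transfer protein 5 (LTP5)
CATMA1a65310	37	4.44	0.14	0.01	3.01e-11	1.64e-29	2.54e-10	AT1G76080	P	thioredoxin family protein
CATMA2a35500	34	3.08	0.13	0.07	2.34e-06	5.32e-13	0.00027	AT2G37220	P	29 kDa ribonucleoprotein
CATMA1a13920	37	2.76	0.13	0.2	8.52e-05	7.32e-05	0.000418	AT1G14890	—	invertase/pectin methylesterase inhibitor family protein
CATMA1a19333	37	3.21	0.14	0.01	3.04e-06	6.27e-22	9.9e-06	AT1G20340	P	plastocyanin
CATMA4a22880	23	2.73	0.14	0.01	3.41e-06	5.25e-25	7.49e-06	AT4G21280	P	PsbQ subunit of photosystem II
CATMA2a04295	38	2.74	0.15	0.03	0.000882	3.72e-19	6.27e-06	AT2G05520	e	glycine-rich protein (GRP)
CATMA5a07300	33	6.42	0.35	0.01	5.78e-05	2.59e-21	1.92e-06	AT5G08050	P	expressed protein
CATMA5a12555	27	3.74	0.18	0.02	8.15e-06	1.76e-21	2.42e-06	AT5G14320	P	30S ribosomal protein S13, chloroplast (CS13)
CATMA4a30310	36	5.11	0.25	0.01	3.41e-06	6.23e-24	4.24e-06	AT4G28660	P	photosystem II reaction centre W (PsbW) family protein
CATMA3b54606	36	2.96	0.17	0.01	0.0216	1.77e-21	5.67e-05	AT3G61470	P	chlorophyll A-B binding protein (LHCA2)
CATMA3a14550	40	3.01	0.19	0.04	7.16e-06	4.96e-20	0.000323	AT3G15190	P	chloroplast 30S ribosomal protein S20
CATMA2a41430	36	3.74	0.22	0.04	3.5e-05	4.69e-18	0.000218	AT2G43030	P	ribosomal protein L3 family protein
CATMA4a26750	18	2.92	0.19	0.03	1.59e-05	2.3e-20	8.52e-05	AT4G25050	P	acyl carrier protein predominantly expressed in leaves
CATMA2a35140	30	3.69	0.23	0.03	2.86e-05	4.06e-18	0.00091	AT2G36870	a,e,w	xyloglucan:xyloglucosyl transferase
CATMA1a63880	31	3.32	0.22	0.04	0.000739	2.67e-18	9.61e-05	AT1G74470	P	geranylgeranyl reductase
CATMA4a18000	32	4.95	0.35	0.01	2.52e-06	1.37e-22	8.09e-06	AT4G16980	e	arabinogalactan-protein family
CATMA5a51450	30	2.74	0.2	0.05	0.0012	8.97e-17	7.88e-05	AT5G55700	P	similar to beta-amylase (CT-BMY)
CATMA4a40410	32	2.58	0.19	0.01	1.3e-05	8.94e-23	0.00019	AT4G38970	a,P	fructose-bisphosphate aldolase
CATMA2a37967	40	2.68	0.2	0.02	1.15e-05	2.09e-22	3.6e-05	AT2G39730	a,n,P,w	RuBisCO activase
CATMA1a36300	39	3.16	0.23	0.01	0.000211	1.04e-22	8.53e-05	AT1G42970	a,P	glyceraldehyde-3-phosphate dehydrogenase B (GAPB)
CATMA1a27050	40	4.2	0.29	0.03	6.6e-07	4.24e-22	7.68e-06	AT1G29070	P	ribosomal protein L34 family protein
CATMA1a64335	34	4.0	0.29	0.03	8.82e-06	1.17e-20	1.03e-05	AT1G74970	P	ribosomal protein S9 (RPS9)
CATMA5a36620	34	4.23	0.32	0.03	3.06e-05	3.96e-21	7.34e-06	AT5G40950	P	50S ribosomal protein L27, chloroplast (RPL27)
CATMA5a39880	34	3.01	0.23	0.07	8.93e-05	1.17e-15	1.19e-07	AT5G44130	w,p	fasciclin-like arabinogalactan-protein
CATMA1a13350	28	3.28	0.26	0.01	1.31e-05	3.61e-19	6.76e-05	AT1G14345	P	expressed protein, one transmembrane domain
CATMA3a11290	38	2.98	0.25	0.02	2.46e-05	5.34e-22	6.59e-05	AT3G12340	P	immunophilin-related
CATMA4a01510	23	2.96	0.25	0.06	2.93e-05	1.7e-18	0.00106	AT4G01310	c,P	ribosomal protein L5 family protein
CATMA4a23520	29	3.77	0.32	0.05	0.0533	1.68e-12	8.7e-05	AT4G21860	P	methionine sulfoxide reductase domain protein
CATMA4a26465	34	4.05	0.35	0.05	2.79e-05	7.36e-18	0.000405	AT4G24770	P	31 kDa ribonucleoprotein
CATMA1a60820	32	3.12	0.27	0.03	0.021	3.18e-19	8.43e-05	AT1G71500	P	Rieske (2Fe-2S) domain-containing protein
CATMA4a17230	37	3.28	0.3	0.03	5.81e-05	1.22e-19	6.59e-05	AT4G16410	—	expressed protein
CATMA2a00475	32	3.43	0.35	0.2	0.000116	1.64e-10	3.85e-05	AT2G01420	—	auxin transport protein
CATMA4a21620	29	2.96	0.3	0.06	0.000323	2.54e-19	8.87e-05	AT4G20360	a,n,P	elongation factor Tu (TUFA)
CATMA1a00590	36	2.96	0.32	0.11	5.48e-05	1.14e-15	1.85e-07	AT1G01610	—	glycerol-3-phosphate acyltransferase
CATMA1a67690	35	2.73	0.29	0.04	0.00294	1.49e-20	8.53e-05	AT1G78630	P	ribosomal protein L13 family protein
CATMA1a67475	33	3.48	0.39	0.23	1.49e-05	5.1e-08	0.000319	AT1G78380	c,P,p,v	glutathione S-transferase, putative
CATMA2a30900	35	2.63	0.31	0.08	1.43e-05	2e-17	0.011	AT2G32180	P	expressed protein
CATMA3a20410	34	2.69	0.32	0.1	8.23e-06	8.91e-16	8.79e-05	AT3G20680	P	expressed protein
CATMA5a19250	39	2.55	0.32	0.17	0.00035	4.39e-14	8.94e-05	AT5G20720	a,M,P	20 kDa chaperonin (CPN21)
CATMA3a52950	31	2.72	0.36	0.21	4.03e-05	7.38e-12	6.45e-05	AT3G59940	—	kelch repeat-containing F-box family protein
CATMA1a30400	31	2.66	0.36	0.01	5e-05	1.33e-23	0.00557	AT1G32060	a,P	phosphoribulokinase (PRK)
CATMA5a43410	23	0.0	17.15	278.19	4.95e-09	2.53e-13	0.046445	AT5G47450	v	major intrinsic family protein
CATMA3a46940	19	0.02	10.04	116.88	7.21e-06	6.92e-12	0.024062	AT3G53980	e	lipid transfer protein (LTP) family protein
CATMA3a00185	23	0.08	12.14	141.58	1.49e-08	8.53e-21	6.09e-06	AT3G01190	e	peroxidase 27 (PER27)
CATMA3a23750	16	0.11	25.69	233.14	1.38e-05	4.82e-16	0.00675	AT3G23800	—	selenium-binding family protein
CATMA1a40940	11	0.14	17.74	11.32	2.3e-05	1.52e-05	0.011573	AT1G49860	c	glutathione S-transferase
CATMA1a28300	19	0.24	4.6	11.59	5.14e-05	2.23e-08	0.021175	AT1G30270	c,n,p	CBL-interacting protein kinase 23 (CIPK23)
CATMA5a08890	20	0.24	32.72	56.89	2.23e-10	6.53e-18	2.93e-05	AT5G10130	e,x	pollen Ole e 1 allergen and extensin family protein
CATMA2a25985	17	0.26	11.72	28.97	5.25e-06	7.78e-13	0.473892	AT2G27550	—	centroradialis protein (CEN)
CATMA1a22610	22	0.28	36.53	105.82	7.83e-06	4.44e-15	0.000233	AT1G23720	w	proline-rich extensin-like family protein
CATMA3a23170	25	0.29	13.03	75.65	7.07e-07	3.96e-21	1.58e-06	AT3G23175	E	lesion inducing protein-related
CATMA1a61170	22	0.3	2.78	3.42	8.77e-07	1.88e-07	0.468587	AT1G71960	p	ABC transporter family protein
CATMA2a37070	24	0.31	11.75	27.66	7.75e-05	3.99e-13	0.000278	AT2G38800	—	calmodulin-binding protein-related
CATMA1a44600	16	0.31	4.16	4.65	4.64e-05	1.63e-05	0.014032	AT1G53590	v	C2 domain-containing protein
CATMA4a10345	14	0.34	17.87	38.52	3.41e-06	2.36e-10	0.071489	AT4G10310	p	sodium transporter (HKT1)
CATMA5a06070	27	0.34	2.56	3.11	3.47e-08	1.77e-11	0.307964	AT5G06850	—	C2 domain-containing protein
CATMA1a04113	20	0.35	2.71	21.16	2.8e-05	8.54e-17	0.079992	AT1G05260	E	peroxidase 3 (PER3)
CATMA1a28520	23	0.36	5.05	5.28	3.41e-06	4e-11	2.69e-05	AT1G30510	P	ferredoxin--NADP(+) reductase
CATMA3a48230	23	0.37	7.91	20.28	2.97e-06	5.49e-15	0.027924	AT3G55230	e	disease resistance-responsive family protein
CATMA5a09320	11	0.37	5.73	13.92	4.28e-08	1.53e-17	2.74e-05	AT5G10580	e	expressed protein
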