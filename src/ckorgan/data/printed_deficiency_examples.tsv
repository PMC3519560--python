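category	probe_id	abb	r_root_CKX1	r_shoot_CKX1	q_genotype	agi	description
root_specific	CATMA5a61330	11	18.32	1.26	0.000799	AT5G65990	amino acid transporter family protein
root_specific	CATMA3a43475	5	7.63	1.57	9.62e-06	AT3G50410	Dof-type zinc finger domain-containing protein
root_specific	CATMA1a62410	4	5.66	0.63	0.0499	AT1G73165	Clavata3 / ESR-Related-1 (CLE1)
root_specific	CATMA5a37900	7	4.72	1.07	0.00477	AT5G42200	zinc finger (C3HC4-type RING finger) family protein
root_specific	CATMA3a40595	4	2.86	0.97	0.00565	AT3G47600	myb family transcription factor (MYB94)
root_specific	CATMA1a66990	9	2.6	0.89	0.00531	AT1G77840	eukaryotic translation initiation factor 5, putative (eIF-5)
root_specific	CATMA4a36496	11	0.27	1.1	0.0104	AT4G34680	GATA transcription factor 3, putative (GATA-3)
root_specific	CATMA2a45310	4	0.02	1.03	0.0177	AT2G46870	DNA-binding protein, putative
shoot_specific	CATMA4a00090	9	1.0	76.53	0.00119	AT4G00080	invertase/pectin methylesterase inhibitor family protein
shoot_specific	CATMA5a49170	9	1.33	15.44	0.00478	AT5G53250	arabinogalactan-protein, putative (AGP22)
shoot_specific	CATMA4a26210	10	1.46	12.59	1.52e-06	AT4G24480	serine/threonine protein kinase, putative
shoot_specific	CATMA4a02865	9	1.01	8.82	0.0027	AT4G02560	homeobox protein LUMINIDEPENDENS (LD)
shoot_specific	CATMA3a15410	4	0.55	8.43	0.0183	AT3G15990	sulfate transporter, putative
shoot_specific	CATMA2a44715	11	1.63	4.29	0.00045	AT2G46340	phytochrome A supressor spa1 (SPA1)
shoot_specific	CATMA2a31150	13	0.68	3.08	0.0172	AT2G32950	COP1 regulatory protein
shoot_specific	CATMA2a00475	14	1.07	0.38	0.0237	AT2G01420	auxin transport protein, putative
shoot_specific	CATMA1a08416	13	0.81	0.33	0.0202	AT1G09570	phytochrome A (PHYA)
shoot_specific	CATMA3a19415	16	1.24	0.33	0.0233	AT3G19820	cell elongation protein DWARF1 / DIMINUTO (DWF1/DIM)
shoot_specific	CATMA5a06800	13	0.59	0.2	2.63e-05	AT5G07580	ERF subfamily B-3 of ERF/AP2 transcription factor
shoot_specific	CATMA4a18523	10	0.72	0.2	0.00223	AT4G17490	ERF subfamily B-3 of ERF/AP2 transcription factor (ATERF-6)
shoot_specific	CATMA2a32570	16	0.69	0.18	0.00182	AT2G34420	chlorophyll A-B binding protein (LHB1B2)
shoot_specific	CATMA4a36460	15	0.99	0.17	0.00319	AT4G34620	ribosomal protein S16 family protein
shoot_specific	CATMA2a24825	13	1.86	0.16	0.0126	AT2G26500	cytochrome b6f complex subunit (petM), putative
shoot_specific	CATMA5a60355	12	0.41	0.15	2.94e-06	AT5G64920	COP1-interacting protein (CIP8)
shoot_specific	CATMA4a22880	9	1.1	0.15	0.0045	AT4G21280	PsbQ subunit of photosystem II
shoot_specific	CATMA5a59535	4	0.59	0.12	0.000199	AT5G64040	photosystem I reaction center subunit PSI-N
shoot_specific	CATMA1a68150	7	0.7	0.11	0.00869	AT1G79040	10 kDa PsbR subunit of photosystem II (PSII)
shoot_specific	CATMA5a43205	16	0.63	0.11	1.37e-05	AT5G47220	ERF subfamily B-3 of ERF/AP2 transcription factor (ATERF-2)
shoot_specific	CATMA1a46750	13	1.38	0.06	0.00391	AT1G55670	photosystem I reaction center subunit V
shoot_specific	CATMA5a43215	15	0.78	0.05	0.00077	AT5G47230	ERF subfamily B-3 of ERF/AP2 transcription factor (ATERF-5)
shoot_specific	CATMA2a43300	11	0.52	0.04	9.62e-06	AT2G44840	ERF subfamily B-3 of ERF/AP2 transcription factor
shoot_specific	CATMA5a57200	11	0.64	0.03	0.0033	AT5G61600	ERF subfamily B-3 of ERF/AP2 transcription factor
shoot_specific	CATMA5a47120	7	0.42	0.03	0.0012	AT5G51190	ERF subfamily B-3 of ERF/AP2 transcription factor
similar	CATMA5a07985	10	16.98	57.3	0.00342	AT5G08640	flavonol synthase 1 (FLS1)
similar	CATMA4a10345	8	24.01	16.17	0.00199	AT4G10310	sodium transporter (HKT1)
similar	CATMA5a52815	11	3.38	33.99	5.78e-05	AT5G57090	auxin transport protein (EIR1) (PIN2)
similar	CATMA2a45915	8	4.11	26.54	0.000582	AT2G47460	subgroup 7 of R2R3-MYB family (MYB12)
similar	CATMA2a32640	11	3.2	25.43	0.000207	AT2G34500	cytochrome P450 family protein
similar	CATMA1a04035	5	3.86	5.95	0.0172	AT1G05180	auxin-resistance protein (AXR1)
similar	CATMA5a12150	15	3.65	4.48	0.000257	AT5G13930	chalcone synthase
similar	CATMA3a11725	8	4.38	3.17	0.0142	AT3G12750	zinc transporter (ZIP1)
similar	CATMA3a54340	14	0.34	0.29	0.0275	AT3G61190	BON1-associated protein 1 (BAP1)
similar	CATMA1a26550	4	0.34	0.26	9.57e-06	AT1G28370	ERF subfamily B-1 of ERF/AP2 transcription factor
similar	CATMA1a09322	10	0.3	0.29	0.00119	AT1G10470	response regulator 4 (ARR4)
similar	CATMA3a16175	16	0.17	0.38	0.00392	AT3G16770	ERF subfamily B-2 of ERF/AP2 transcription factor (RAP2.3)
similar	CATMA5a04585	11	0.21	0.31	0.0073	AT5G05410	DREB subfamily A-2 of ERF/AP2 transcription factor (DREB2A)
similar	CATMA3a14565	15	0.26	0.2	0.004	AT3G15210	ERF subfamily B-1 of ERF/AP2 transcription factor (ATERF-4)
similar	CATMA5a58475	5	0.11	0.29	0.000622	AT5G62920	response regulator (ARR6)
similar	CATMA1a66910	8	0.28	0.09	0.000772	AT1G77760	nitrate reductase 1 (NR1)
similar	CATMA1a57435	6	0.12	0.18	0.00118	AT1G68050	F-box family protein (FKF1) / adagio 3 (ADO3)
similar	CATMA1b35155	7	0.19	0.05	0.000813	AT1G37130	nitrate reductase 2 (NR2)
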