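gene_id	annotation	symbol	lfc_th_vs_ctrl	q_th_vs_ctrl	lfc_thchx_vs_chx	q_thchx_vs_chx
1-2.c12061_1_1454	Mucin-19	MUC19	1.836	2.24e-06	1.1971	7.78e-05
1-2.c14617_5_1744	Thyroid hormone receptor beta	TRbeta	4.96	0.000225	2.75	0.009164
1-2.c18325_5_1432	Cellular communication network factor 4	CCN4	2.8591	2.39e-10	1.4166	7.07e-08
1-2.c29621_1_1669	Phosphoribosylformylglycinamidine synthase	PFAS	1.4898	0.00025478	2.9301	1.42e-19
1-2.c40374_1_1646	Cytochrome P450 2K6	CYP2K6	3.4304	5.71e-08	1.8504	0.00055797
1-2.c48220_1_1626	Thyroid hormone-induced bzip protein	TH/BZIP	6.8902	7.79e-36	4.5078	2.34e-23
1-2.c49674_1_1423	SRY-box 4	SOX4	1.6237	5.45e-11	1.0687	4.52e-12
1-2.c51085_1_1665	Aldo-keto reductase family 1 member C1 homolog	AKR1C1	3.3202	4.03e-07	2.6031	7.47e-05
1-2.c5151_6_1369	BTB/POZ domain-containing protein KCTD1	KCTD1	4.0778	1.74e-14	3.4215	5.18e-26
2-3.c10814_9_2303	HIG1 domain family member 1C	HIGD1C	2.0233	4.56e-17	1.5861	6.19e-20
2-3.c13088_1_2345	Xenopus tropicalis clone ISB-376E5		4.5116	1.77e-09	2.8316	8.01e-07
2-3.c14039_1_2467	Cyclic AMP-responsive element-binding protein 3-like protein	CREB3L2	1.1192	0.011793	1.0293	0.020369
2-3.c15607_1_2004	Matrix Gla protein	MGP	2.2257	1.89e-12	1.4194	2.14e-06
2-3.c22743_1_2511	Domain of unknown function		1.0446	4.72e-05	1.1645	9.09e-07
2-3.c25947_1_2264	Integrase core domain		3.1629	8.27e-36	2.0716	3.45e-23
2-3.c28146_1_1987	High mobility group AT-hook 2	HMGA2	2.2612	2.49e-50	1.5387	8.26e-20
2-3.c29527_1_2235	Nuclear factor I B	NFIB	2.0185	1.80e-20	1.1458	0.00079244
2-3.c33125_1_2127	Prolactin-releasing peptide		2.2236	7.57e-16	1.2502	9.35e-09
2-3.c35212_1_1923	30S ribosomal protein Thx		6.2648	5.50e-06	1.8219	0.019126
2-3.c3870_2_2171	High mobility group protein HMGI-C isoform X1	HMGI-C	3.2162	5.44e-08	1.4332	0.0063144
2-3.c40223_1_2454	Primase zinc finger		1.9637	0.0070026	2.5371	1.71e-05
2-3.c41889_1_2446	Phospholysine phosphohistidine inorganic pyrophosphate phosphatase-like isoform X1		8.053	1.30e-23	2.8319	3.54e-42
2-3.c46259_1_2693	LINE-1 retrotransposable element ORF2 protein	POL	3.5154	1.61e-43	2.4839	1.25e-12
2-3.c46777_1_2141	Cytochrome P450 2K4-like	CYP2K4	3.7652	3.02e-14	5.3556	3.21e-06
2-3.c49466_1_2588	Bone gamma-carboxyglutamate protein, osteocalcin	BGLAP	4.58	2.93e-05	3.85	4.32e-05
2-3.c49620_1_2429	A-agglutinin-binding subunit Aga2		2.5667	5.68e-17	1.9347	4.84e-09
2-3.c49900_1_2283	Chemokine-like receptor 1	CMKLR1	2.8313	0.00050004	2.1867	0.0024274
2-3.c54695_1_2043	Herpesvirus latent membrane protein 1	LMP1	6.7631	3.54e-07	5.2217	1.70e-21
2-3.c54887_1_2006	Endosialin-like		5.3677	3.01e-103	4.8179	1.81e-162
2-3.c56689_1_2256	Spastic paraplegia 20	SPG20	2.3087	1.16e-05	1.1046	0.01316
2-3.c59493_1_2681	Interferon-induced transmembrane protein		2.0567	3.01e-24	1.4189	6.19e-15
2-3.c59735_1_1918	Dual specificity protein phosphatase 9	DUSP9	1.5732	0.042605	1.0431	0.028172
2-3.c60998_2_1874	Serine protease	HTRA1	2.1584	1.34e-12	1.3218	8.01e-05
2-3.c8238_1_2510	Streptopelia turtur genome assembly, chromosome: Z		4.5727	7.72e-59	1.3346	2.68e-19
2-3.c8249_11_2151	Trimethyllysine dioxygenase	TMLHE	1.3585	3.27e-09	1.3164	2.25e-06
3-6.c13750_1_2763	Nanorana parkeri uncharacterized LOC108785573		4.7756	3.73e-13	3.3546	1.11e-17
3-6.c5228_1_3273	Neuronal regeneration related protein	NREP	4.6538	1.94e-89	1.6176	1.72e-36
3-6.c5722_1_2767	Hematopoietic prostaglandin D synthase	HPGDS	2.7747	4.67e-39	1.0969	0.0077565
3-6.c6057_1_8371	Kruppel-like factor 9	KLF9	3.8933	1.95e-16	1.4259	4.52e-07
1-2.c9181_5_1822	Type II keratin, basic	KRT2	-1.1652	0.001047	-1.5553	0.001456
1-2.c9370_4_1536	Type I keratin, acidic	KRT1	-2.2548	7.56e-12	-2.271	0.02986
2-3.c2430_14_2348	Calpain-9	CAPN9	-1.3212	3.15e-05	-1.8402	0.004251
2-3.c46963_1_2178	Actin beta/gamma 1	ACTB_G1	-3.3006	0.009307	-2.539	0.042791
3-6.c14529_1_2954			-1.047	0.030231	-3.9806	0.021854
3-6.c17071_1_3282	Endothelin receptor type B	EDNRB	-1.8683	7.62e-05	-1.1902	0.022074
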