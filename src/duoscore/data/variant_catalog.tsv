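rsid	gene	major	minor	maf_mothers	maf_children	maf_ceu	risk_orientation	traits	fg_weight	t2d_weight	proxy_rsid	proxy_r2	alias	notes
rs4607103	ADAMTS9	C	T	0.24	0.24	0.19	major	t2d		0.09
rs2877716	ADCY5	C	T	0.26	0.26	0.25	major	fasting_glucose,t2d	0.027	0.11	rs11708067	0.8		weights taken from the linked index SNP
rs1501299	ADIPOQ	G	T		0.27	0.27	minor	t2d					typed in children only
rs17300539	ADIPOQ	G	A		0.09	0.08	minor	t2d					typed in children only
rs266729	ADIPOQ	C	G		0.26	0.31	minor	t2d					typed in children only
rs10885122	ADRA2A	G	T	0.13	0.12	0.10	major	fasting_glucose	0.022
rs11071657	C2CD4B	A	G	0.39	0.38	0.41	major	fasting_glucose	0.008
rs12779790	CDC123/CAMK1D	A	G	0.18	0.19	0.22	minor	t2d					excluded from T2DGRS: low maternal sample size
rs10946398	CDKAL1	A	C	0.31	0.31	0.30	minor	t2d		0.15
rs10811661	CDKN2A/B	T	C	0.18	0.17	0.20	major	t2d		0.23
rs20417	COX2	G	C	0.15	0.15	0.18	major	t2d					excluded from T2DGRS: effect estimated in Pima Indians only
rs11605924	CRY2	C	A	0.48	0.48	0.54	minor	fasting_glucose	0.015
rs2191349	DGKB/TMEM195	T	G	0.46	0.46	0.53	major	fasting_glucose,t2d	0.03	0.06
rs174550	FADS1	T	C	0.33	0.33	0.37	major	fasting_glucose	0.017
rs9939609	FTO	T	A	0.40	0.40	0.45	minor	obesity					obesity variant; in neither score
rs560887	G6PC2	C	T	0.30	0.30	0.33	major	fasting_glucose	0.075
rs1799884	GCK	G	A	0.18	0.18	0.20	minor	fasting_glucose,t2d	0.062	0.07	rs4607517	1.0		FG weight from rs4607517; T2D weight from linked rs917793
rs780094	GCKR	C	T	0.39	0.39	0.38	major	fasting_glucose,t2d	0.029	0.06
rs7034200	GLIS3	C	A	0.47	0.48	0.53	minor	fasting_glucose	0.018
rs1111875	HHEX-IDE	C	T	0.41	0.41	0.44	major	t2d		0.16
rs757210	HNF1B	C	T	0.37	0.37	0.43	minor	t2d		0.1
rs4402960	IGF2BP2	G	T	0.31	0.30	0.29	minor	t2d		0.16			rs4402690
rs864745	JAZF1	A	G	0.50	0.50	0.48	major	t2d		0.1
rs5219	KCNJ11	C	T	0.35	0.35	0.50	minor	t2d		0.15
rs2237892	KCNQ1	C	T	0.06	0.06	0.08	major	t2d					excluded from T2DGRS: strong LD with rs2237895
rs2237895	KCNQ1	A	C	0.42	0.41	0.36	minor	t2d		0.22
rs7944584	MADD	A	T	0.28	0.28	0.29	major	fasting_glucose	0.021
rs10830963	MTNR1B	C	G	0.27	0.28	0.30	minor	fasting_glucose,t2d	0.067	0.09
rs10923931	NOTCH2	G	T	0.11	0.11	0.09	minor	t2d		0.12
rs1801282	PPARG	C	G	0.12	0.11	0.07	major	t2d		0.17
rs340874	PROX1	C	T	0.43	0.43	0.44	major	fasting_glucose,t2d	0.013	0.07
rs11920090	SLC2A2	T	A	0.12	0.13	0.13	major	fasting_glucose	0.02
rs13266634	SLC30A8	C	T	0.30	0.30	0.25	major	fasting_glucose,t2d	0.027	0.14
rs12255372	TCF7L2	G	T	0.29	0.29	0.22	minor	fasting_glucose					excluded from FGGRS: strong LD with rs7903146
rs7903146	TCF7L2	C	T	0.30	0.30	0.25	minor	fasting_glucose,t2d	0.023	0.31
rs7578597	THADA	A	G	0.11	0.11	0.08	major	t2d		0.14
rs7961581	TSPAN8/LGR5	T	C	0.28	0.28	0.23	minor	t2d		0.09
rs10010131	WFS1	G	A	0.40	0.40	0.26	major	t2d		0.1
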