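gene	location	snp	aa_change	frequency_pct	rs_id	provean	sift	provean_flagged	sift_flagged	variant_type
CYP2D50-1	g.92	G>A	R31H	3.47		-3.134	0.05	1	1	snv
CYP2D50-1	g.134	G>A	G45E	0.69		-3.972	0.02	1	1	snv
CYP2D50-1	g.2605	C>A	Q269K	1.39	rs1148503187	-3.289	0.05	1	1	snv
CYP2D50-1	g.3328	G>C	G376A	0.69		-3.397	0.25	1	0	snv
CYP2D50-1	g.4192	C>A	Q475K	1.39	rs1137288236	-3.149	0.09	1	0	snv
CYP2D50-1	g.4226	C>T	T486I	7.64		2.112	0.36	0	0	snv
CYP2D50-1	g.4228	C>G	L487V	7.64		-1.340	0.35	0	0	snv
CYP2D50-1	g.4235	C>T	S489F	0.69		-2.281	0.11	0	0	snv
CYP2D50-1	g.4240	T>G	S491A	42.36	rs396861920	-0.461	0.65	0	0	snv
CYP2D50-1	g.4255	T>A	C496S	7.64	rs394932323	-8.369	0.00	1	1	snv
CYP2D82	g.83	G>A	R28Q	18.06	rs1141439398	-3.327	0.09	1	0	snv
CYP2D82	g.85	C>T	R29C	0.69	rs1150936359	-6.934	0.00	1	1	snv
CYP2D82	g.1888	C>G	R126G	12.50		-2.807	0.20	1	0	snv
CYP2D82	g.1892	A>C	Y127S	1.39		-6.190	0.22	1	0	snv
CYP2D82	g.1984	G>C	E158Q	5.56	rs1143153764	-1.719	0.27	0	0	snv
CYP2D82	g.2214	T>G	L204R	5.56	rs1138659802	2.658	0.65	0	0	snv
CYP2D82	g.2628	C>T	L233F	1.39		-2.615	0.03	1	1	snv
CYP2D82	g.2635	A>G	H235R	1.39	rs1147081710	-1.112	1.00	0	0	snv
CYP2D82	g.2646	G>C	V239L	0.69		1.753	1.00	0	0	snv
CYP2D82	g.2650	C>T	A240V	0.69		-1.128	1.00	0	0	snv
CYP2D82	g.2673	A>G	K248E	5.56	rs1145722969	-2.428	0.21	0	0	snv
CYP2D82	g.2674	A>G	K248R	54.86	rs1143545655	-0.972	0.20	0	0	snv
CYP2D82	g.2673-2675	AAG>GGA	K248G	0.72		-4.673	0.04	1	1	mnv
CYP2D82	g.2691	C>G	L254V	68.06	rs394128659	-1.482	0.72	0	0	snv
CYP2D82	g.2703	C>G	L258V	34.03		-0.395	0.55	0	0	snv
CYP2D82	g.2733	A>G	T268A	1.39	rs1136055998	1.527	1.00	0	0	snv
CYP2D82	g.2767	T>A	L279Q	1.39	rs1142815816	-5.151	0.00	1	1	snv
CYP2D82	g.3403	T>C	C355R	68.06	rs396631299	4.494	0.74	0	0	snv
CYP2D82	g.3469	T>G	L377V	9.72	rs1148651933	0.477	1.00	0	0	snv
CYP2D82	g.3472	A>G	T378A	9.72	rs1136958956	-0.329	0.46	0	0	snv
CYP2D82	g.3474-3484	CCACATGACAT del	378 fs	0.69						del
CYP2D82	g.3493	A>G	I385V	68.75	rs395645145	-0.035	0.17	0	0	snv
CYP2D82	g.4104	C>T	R417C	22.22	rs1148309512	-4.238	0.02	1	1	snv
CYP2D82	g.4141	G>A	R429H	5.56	rs1145664752	-0.548	0.61	0	0	snv
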