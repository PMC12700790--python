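proband	stutter_status	gene	isoform	cdna_change	protein_change	mis_z	maf	mcap	revel	primateai	alphamissense	gerp	consurf	ndd_gene	criteria	classification
RESTART_15	P	PRPF8	NM_006445	c.A3364G	p.N1122D	8.3	0	D	D	D	D	5.31	9	yes	PS2, PM2, PP2, PP3	Likely pathogenic
RESTART_47	P	CHD4	NM_001273	c.A2477G	p.N826S	6.3	8.0e-6	D	T	D	T	4.9	5	yes	PS2, PP2, PP3, BP4	VUS
RESTART_56	P	UNC13A	NM_001080421	c.T224C	p.V75A	5.6	0	D	D	T	A	4.98	7	no	-	-
KST_2	P	EIF2AK4	NM_001013703	c.G3040A	p.V1014M	2.7	0	T	T	T	T	5.82	8	no	-	-
KST_4	P	GIT1	NM_001085454	c.G2135T	p.R712L	3.1	0	D	T	T	A	4.65	9	no	-	-
KST_7	P	ADGRB1	NM_001702	c.G1441T	p.A481S	4.5	4.2e-6	T	T	T	T	3.55	4	no	-	-
KST_10	P	TUT4	NM_015269	c.A1442T	p.D481V	2.8	0	D	T	T	A	5.51	7	no	-	-
RESTART_18	T	PLXNA1	NM_032242	c.G3182C	p.S1061T	3.4	0	D	D	T	A	3.84	7	yes	PS2, PM2, PP2, PP3, BP4	VUS
RESTART_20	T	TRIO	NM_007118	c.G4520A	p.R1507Q	5.3	3.2e-5	D	D	D	D	5.39	9	yes	PS2, PP2, PP3	Likely pathogenic
RESTART_22	T	NCDN	NM_001014839	c.C2095T	p.R699W	3.8	0	D	T	T	T	5.13	1	yes	PS2, PM2, PP2, BP4	VUS
RESTART_27	T	ZBTB7A	NM_015898	c.C1200G	p.H400Q	4.0	0	D	D	D	D	4	9	yes	PS2, PM2, PP2, PP3	Likely pathogenic
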