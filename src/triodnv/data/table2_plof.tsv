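proband	stutter_status	gene	variant_type	isoform	cdna_change	protein_change	pli	loeuf	maf	ndd_gene	ndd_lof_mechanism	criteria	classification
RESTART_11	P	FLT3	stop_gain	NM_004119	c.A520T	p.R174X	0.61	0.35	0	no	no	-	Variant of interest in GUS
MEGS_14	P	SPTBN1	stop_gain	NM_003128	c.G5678A	p.W1893X	1.00	0.09	0	yes	yes	PVS1, PS2, PM2	Pathogenic
RESTART_8	A	IREB2	frameshift	NM_004136	c.619delC	p.P207QfsTer9	1.00	0.22	0	no	no	-	Variant of interest in GUS
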