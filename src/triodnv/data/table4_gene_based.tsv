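gene	n_snps	p_node	p_edge
GNPTAB	252	0.012	0.23
AP4E1	307	0.011	0.014
IFNAR1	196	0.69	0.33
ARMC3	338	0.24	0.12
ZBTB20	1641	0.049	0.0014
PPID	44	0.027	0.42
SPTBN1	761	5.49e-4	5.84e-4
PRPF8	197	0.54	0.60
TRIO	1070	0.042	0.39
ZBTB7A	101	4.03e-5	9.38e-5
FLT3	520	0.62	0.52
IREB2	188	0.53	0.60
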