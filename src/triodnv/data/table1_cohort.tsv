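cohort	n_total	n_persistent	n_transient	n_ambiguous
RESTART	57	19	30	8
MEGS	16	16	0	0
KST	12	12	0	0
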