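9646cc57f62bcbfdb99be553e438c8956746ba2f148c8d04885b8f57e3e8cc08  table1_cohort.tsv
ba66e80c61ab39a505f7701286a4b656b7045d64abf280e54ff4e75ba2382d7d  table2_plof.tsv
c0840e9fc516738289cf85aa89be4e6d9bffb4264a9df3054558bc5fa09fe8ea  table3_missense.tsv
0d06f51c0f3eae3b36b8e6c2065a510209478e3f9de264b8c07f28e50b9753c4  table4_gene_based.tsv
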