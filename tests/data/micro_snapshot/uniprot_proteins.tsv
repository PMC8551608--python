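# drugpath-snapshot v1
accession	gene_symbol	reviewed	human
P10001	GENE1	true	true
P10002	GENE2	true	true
P10003	GENE3	true	true
P10004	GENE4	true	true
P10005	GENE5	true	true
P10006	GENE6	true	true
P10007	GENE7	true	true
P10008	GENE8	true	true
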