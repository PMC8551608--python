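# drugpath-snapshot v1
gene_symbol	tissue	ntpm
GENE1	heart	3.00
GENE2	heart	1.00
GENE3	heart	20.00
GENE4	heart	0.50
GENE5	heart	2.00
GENE6	heart	0.00
GENE7	heart	5.00
GENE8	heart	0.00
GENE1	liver	0.00
GENE2	liver	4.00
GENE3	liver	0.20
GENE4	liver	8.00
GENE5	liver	1.50
GENE6	liver	30.00
GENE7	liver	0.00
GENE8	liver	2.00
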