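# drugpath-snapshot v1
drug_id	target_accession	gene_symbol	pchembl	organism_class	target_type	family_members	evidence
CHEMBL1001	P10001	GENE1	5.00	human	single_protein		assay
CHEMBL1001	FAM0001		7.00	human	protein_family	P10002;P10003	assay
CHEMBL1001		Gene4	6.20	mammal_nonhuman	single_protein		assay
CHEMBL1002	P10005	GENE5	4.90	human	single_protein		assay
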