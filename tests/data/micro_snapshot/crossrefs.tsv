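# drugpath-snapshot v1
namespace_a	id_a	namespace_b	id_b
chembl	CHEMBL1001	drugbank	DB00001
chembl	CHEMBL1002	pubchem_cid	555
chembl	CHEMBL1002	pharmgkb	PA0001
chembl	CHEMBL1002	iuphar_ligand	301
uniprot_name	GENE5_HUMAN	uniprot_accession	P10005
iuphar_target	2472	uniprot_accession	P10004
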