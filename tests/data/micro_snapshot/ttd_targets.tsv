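# drugpath-snapshot v1
ttd_id	pubchem_cid	uniprot_name
D00001	555	GENE5_HUMAN
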