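# drugpath-snapshot v1
drugbank_id	accession
DB00001	P10001
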