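# drugpath-snapshot v1
ligand_id	target_id
301	2472
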