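R-HSA-9000001	R-HSA-9000002
R-HSA-9000001	R-HSA-9000003
R-HSA-9000001	R-HSA-9000004
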