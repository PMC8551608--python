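R-HSA-9000001	Generic signalling	P10001	P10002	P10003	P10004	P10005	P10006	P10007	P10008
R-HSA-9000002	Alpha cascade	P10001	P10002	P10003
R-HSA-9000003	Beta transport	P10004	P10005	P10006
R-HSA-9000004	Gamma secretion	P10007	P10008
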