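molecule_chembl_id,Names,stIds,fdrs,pValues
CHEMBL1001,Alpha cascade,R-HSA-9000002,0.0357143,0.0178571
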