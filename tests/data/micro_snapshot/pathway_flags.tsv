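st_id	is_disease	species_tax_id
R-HSA-9000001	false	9606
R-HSA-9000002	false	9606
R-HSA-9000003	false	9606
R-HSA-9000004	true	9606
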