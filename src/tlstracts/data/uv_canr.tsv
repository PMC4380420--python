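# tlstracts catalog
# 161 independent UV-induced canavanine-resistance mutants from the same
# irradiated populations (no TLS at the reversion site): the
# lesion-independent control for the chromosomal assay.
# assay_id: UV-canr
# n_products: 161
# strand_convention: coding
assay_id	product_id	record_type	d	change	note
UV-canr	CANR-001	mutation	-1774	A → T	
UV-canr	CANR-002	mutation	-181	T → C	
UV-canr	CANR-003	mutation	621	C → T	
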