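# tlstracts catalog
# 456 products of the matched lesion-free control plasmid (bubble-allele
# design); every product carries the control allele at the lesion-equivalent
# site, so no event rows are listed.
# assay_id: THF-control
# n_products: 456
# strand_convention: complementary
assay_id	product_id	record_type	d	change	note
THF-control	CTRL-001	mutation	-498	A del	
THF-control	CTRL-002	mutation	-460	C → T	
THF-control	CTRL-003	mutation	-368	C ins	
THF-control	CTRL-004	mutation	-325	T del	
THF-control	CTRL-005	mutation	-221	C → G	
THF-control	CTRL-006	mutation	-34	C → T	
THF-control	CTRL-007	mutation	236	A → G	
THF-control	CTRL-008	mutation	376	G del	
THF-control	CTRL-009	mutation	498	A del	
THF-control	CTRL-010	mutation	610	T → C	
THF-control	CTRL-011	mutation	784	T del	
THF-control	CTRL-012	mutation	907	C → T	
THF-control	CTRL-013	mutation	1012	C → T	
THF-control	CTRL-014	mutation	1209	G → T	
THF-control	CTRL-015	mutation	1242	C → T	
THF-control	CTRL-016	mutation	1447	A → C	
THF-control	CTRL-017	mutation	1621	C → T	
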