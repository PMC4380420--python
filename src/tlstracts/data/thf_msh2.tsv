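# tlstracts catalog
# 47 bypass products from mismatch-repair-deficient (msh2) cells;
# the 220-nt downstream region was sequenced and no mutations were found.
# assay_id: THF-plasmid-msh2
# n_products: 47
# strand_convention: complementary
assay_id	product_id	record_type	d	change	note
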