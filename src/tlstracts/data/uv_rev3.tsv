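# tlstracts catalog
# 231 UV-induced revertants lacking the extension polymerase (rev3);
# the downstream kilobase was sequenced and no mutations were found.
# assay_id: UV-chrV-rev3
# n_products: 231
# strand_convention: coding
assay_id	product_id	record_type	d	change	note
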