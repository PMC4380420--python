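# tlstracts catalog
# 165 UV-induced revertants lacking the alternative TLS polymerase
# (rad30); five downstream mutations were reported spanning distances
# 505-1026 nt.  Only the span is published: the interior positions and
# the change descriptors below are synthetic placeholders (endpoints kept).
# assay_id: UV-chrV-rad30
# n_products: 165
# strand_convention: coding
assay_id	product_id	record_type	d	change	note
UV-chrV-rad30	RAD30-001	mutation	505	G → A	synthetic position
UV-chrV-rad30	RAD30-002	mutation	635	G → A	synthetic position
UV-chrV-rad30	RAD30-003	mutation	765	G → A	synthetic position
UV-chrV-rad30	RAD30-004	mutation	895	G → A	synthetic position
UV-chrV-rad30	RAD30-005	mutation	1026	G → A	synthetic position
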