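gene	rsid	chrom	risk_allele	raf	or
HLA-DRB	rs3135388	6	T	0.14	2.53
EVI5	rs10735781	1	G	0.33	1.19
CLEC16A	rs64981169	16	G	0.33	1.27
CD58	rs12044852	1	C	0.88	1.50
IL7R	rs6897932	5	C	0.72	1.21
IL2RA	rs2104286	10	A	0.73	1.14
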