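gene	rsid	chrom	risk_allele	raf	or
MMEL1	rs4648356	1	C	0.67	1.14
EVI5	rs11810217	1	A	0.25	1.15
CD58	rs1335532	1	A	0.87	1.22
RGS1	rs1323292	1	A	0.83	1.12
KIF21B	rs7522462	1	G	0.70	1.11
CBLB	rs2028597	3	G	0.91	1.13
TMEM39A	rs2293370	3	G	0.80	1.13
IL12A	rs2243123	3	G	0.29	1.08
IL7R	rs6897932	5	G	0.73	1.11
PTGER4	rs4613763	5	G	0.13	1.20
HLA-DRB	rs3135388	6	A	0.13	3.08
OLIG3	rs13192841	6	A	0.27	1.10
IL7	rs1520333	8	G	0.25	1.10
IL2RA	rs3118470	10	G	0.32	1.12
ZMIZ1	rs1250550	10	A	0.35	1.10
CD6	rs650258	11	G	0.63	1.12
TNFRSF1A	rs1800693	12	G	0.40	1.12
CYP27B1	rs12368653	12	A	0.47	1.10
MPHOSPH9	rs949143	12	G	0.28	1.08
CLEC16A	rs7200786	16	A	0.46	1.15
IRF8	rs13333054	16	A	0.23	1.11
STAT3	rs9891119	17	C	0.36	1.11
TYK2	rs8112449	19	G	0.67	1.08
CD40	rs2425752	20	A	0.25	1.11
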