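gene	rsid	chrom	risk_allele	raf	or
VCAM1	rs11581062	1	G	0.29	1.12
No gene	rs12466022	2	C	0.73	1.11
PLEK	rs7595037	2	A	0.55	1.11
MERTK	rs17174870	2	G	0.75	1.11
SP140	rs10201872	2	A	0.18	1.14
No gene	rs669607	3	C	0.48	1.13
EOMES	rs11129295	3	A	0.36	1.11
CD86	rs9282641	3	G	0.91	1.21
IL12B	rs2546890	5	A	0.52	1.11
BACH2	rs12212193	6	G	0.47	1.09
THEMIS	rs802734	6	A	0.69	1.10
MYB	rs11154801	6	A	0.36	1.13
IL22RA2	rs17066096	6	G	0.24	1.14
TAGAP	rs1738074	6	G	0.57	1.13
ZNF746	rs354033	7	G	0.74	1.11
MYC	rs4410871	8	G	0.72	1.11
PVT1	rs2019960	8	G	0.23	1.12
HHEX	rs7923837	10	G	0.62	1.10
CLECL1	rs10466829	12	A	0.50	1.09
ZFP36L1	rs4902647	14	G	0.53	1.11
BATF	rs2300603	14	A	0.74	1.11
GALC	rs2119704	14	C	0.92	1.22
MALT1	rs7238078	18	A	0.77	1.12
TNFSF14	rs1077667	19	G	0.79	1.16
MPV17L2	rs874628	19	A	0.72	1.11
DKKL1	rs2303759	19	C	0.25	1.11
CYP24A1	rs2248359	20	G	0.61	1.12
MAPK1	rs2283792	22	C	0.52	1.10
ODF3B	rs140522	22	A	0.33	1.10
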