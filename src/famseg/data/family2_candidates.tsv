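filter	gene	position	ref	alt	rsid	type	change	mmaf	cadd
1	AKR1B1	chr7:134136457	C	T	rs201718247	missense	NM_001628:c.G115A:p.G39R	0.00083	34
1	SLC25A25	chr9:130864666	C	T	rs748220703	missense	NM_001006641:c.C494T:p.T165M	0.0004	34
1	RYR3	chr15:33893707	C	T	rs760906719	missense	NM_001036:c.C1876T:p.R626W	0.00041	34
1	RUFY1	chr5:178987155	A	T	rs754852607	missense	NM_001040451:c.A116T:p.Q39L	0.00008	28.6
1	TIPIN	chr15:66641436	T	C	rs200514985	missense	NM_001289986:c.A134G:p.D45G	0.00041	27.9
1	C1orf228	chr17:45166747	C	T	rs575641425	missense	NM_001145636:c.C595T:p.P199S	0.00041	26.3
1	HECTD4	chr12:112677734	T	C	rs779868916	missense	NM_001109662:c.A4654G:p.I1552V	0.00002	25.2
1	BCL6	chr3:187444624	T	C	rs747910667	missense	NM_001130845:c.A1603G:p.R535G	0.0001	23.4
1	CA12	chr15:63618533	C	T	rs149256486	missense	NM_001293642:c.G803A:p.G268E	0.0002	23.3
2	UTP11L	chr1:38489295	C	T	rs771377582	missense	NM_016037:c.C757T:p.R253C	0.0002	35
2	PAX7	chr1:18961015	G	A	rs369607271	missense	NM_001135254:c.G304A:p.G102S	0.00008	34
2	FNDC3B	chr3:171969145	C	T	rs190147254	missense	NM_001135095:c.C604T:p.R202C	0.00083	31
2	ZMYM4	chr1:35836075	G	A	.	missense	NM_005095:c.G1028A:p.G343D	0	24.6
2	WDFY4	chr10:50013303	A	G	rs748753983	splicing	.	0.00005	23.7
2	NSD2	chr4:1957024	C	G	rs748922675	missense	NM_001042424:c.C2475G:p.H825Q	0.00041	23.6
2	MED14	chrX:40552004	G	A	rs763899660	missense	NM_004229:c.C1801T:p.R601C	0.00026	22.7
2	C17orf53	chr17:42225596	G	A	rs377372267	missense	NM_001171251:c.G425A:p.S142N	0.0004	21.8
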