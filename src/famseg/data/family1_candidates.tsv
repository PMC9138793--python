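filter	gene	position	ref	alt	rsid	type	change	mmaf	cadd
1	FBXL4	chr6:993222281	A	C	rs757154231	missense	NM_012160:c.T1739G:p.L580R	0.00001	32
1	UBASH3A	chr21:43857670	C	T	rs201756769	missense	NM_001001895:c.C1352T:p.T451M	0.0002	30
1	MYH13	chr17:10206712	T	C	rs767313943	missense	NM_003802:c.A5570G:p.Q1857R	0.00002	27.1
1	FRZB	chr2:183699592	C	T	rs150679557	missense	NM_001463:c.G962A:p.R321Q	0.00083	24.3
1	TAF1C	chr16:84213125	G	A	rs61730960	missense	NM_001243158:c.C1036T:p.R346W	0.00041	24.3
1	STRADB	chr2:202337785	C	G	rs369992593	missense	NM_001206864:c.C301G:p.L101V	0.00008	23.6
1	CLK1	chr2:201726049	C	A	rs141755850	missense	NM_001162407:c.G428T:p.S143I	0.00041	23
2	SPTLC3	chr20:13074186	G	A	rs372930777	missense	NM_018327:c.G788A:p.R263Q	0.00008	35
2	CAPN2	chr1:223947063	A	G	.	missense	NM_001146068:c.A1175G:p.E392G	0	34
2	COL17A1	chr10:105807514	C	T	rs757388768	missense	NM_000494:c.G2318A:p.G773E	0.00041	34
2	HCLS1	chr3:121363691	C	T	rs757006680	missense	NM_001292041:c.G373A:p.G125R	0.00001	34
2	STARD9	chr15:42930971	C	T	rs369566419	missense	NM_020759:c.C520T:p.R174W	0.0001	33
2	CNST	chr1:246829203	C	T	rs766380272	missense	NM_152609:c.C2174T:p.S725F	0.00001	28.4
2	STXBP5L	chr3:120976023	C	T	rs184420053	missense	NM_001308330:c.C1675T:p.L559F	0.00083	26.4
2	DNAH3	chr16:20975280	G	A	rs376279103	missense	NM_017539:c.C9926T:p.S3309L	0.00008	26
2	TENM4	chr11:78383268	G	A	rs747100917	missense	NM_001098816:c.C5603T:p.A1868V	0.00001	25.6
2	MYOM3	chr1:24421405	G	C	rs200854393	missense	NM_152372:c.C866G:p.S289C	0.0004	25.1
2	ASIC2	chr17:31351024	C	T	rs199589382	missense	NM_001094:c.G1051A:p.A351T	0.0002	23.8
2	NMRK2	chr19:3933697	T	G	.	splicing	.	0	23.8
2	APOB	chr2:21252574	C	A	rs778274241	missense	NM_000384:c.G1554T:p.K518N	0.00002	23.4
2	DERL2	chr17:5384651	C	T	rs202210923	missense	NM_001304777:c.G289A:p.V97I	0.00083	22.9
2	RIC1	chr9:5762545	G	A	rs771929691	missense	NM_001206557:c.G1886A:p.R629H	0.00041	22.8
2	DLL3	chr19:39996056	G	A	.	missense	NM_016941:c.G1058A:p.R353K	0	22.4
2	TMEM143	chr19:48863405	G	A	rs544787964	missense	NM_001303539:c.C293T:p.A98V	0.00083	20.2
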