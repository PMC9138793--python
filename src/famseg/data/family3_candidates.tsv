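filter	gene	position	ref	alt	rsid	type	change	mmaf	cadd
1	PRKD1	chr14:30108088	A	C	.	missense	NM_001330069.2:c.743T>G:p.F248C	0	22.3
2	TNRC6C	chr17:76094616	C	T	rs367710467	missense	NM_001142640.1:c.4607C>T:p.S1536L	0	33
2	STAB1	chr3:52554136	G	C	.	missense	NM_015136.3:c.5412G>C:p.E1804D	0	33
2	THOP1	chr19:2799789	G	A	.	missense	NM_003249.5:c.589G>A:p.G197R	0	33
2	SPDYA	chr2:29072798	TG	T	.	splicing	NM_001142634.2:c.934del:p.E312KfsTer20	0	32
2	TMX2-CTNND1	chr11:57505465	C	T	rs375390370	missense	NM_001347890.1:c.331C>T:p.R111C	0	32
2	ZNF793	chr19:38023257	G	A	rs200503532	splicing	NM_001013659.3:c.16-1G>A	0	32
2	NOMO3	chr16:16363998	C	T	.	missense	NM_001004067.4:c.1915C>T:p.R639C	0.00017	32
2	USP17L10	chr4:9213003	T	A	.	nonsense	NM_001256852.1:c.621T>A:p.C207Ter	0	32
2	CNR2	chr1:24201377	G	A	rs201829495	missense	NM_001841.3:c.731C>T:p.A244V	0	28.2
2	ZNF507	chr19:32845840	T	C	.	missense	NM_001136156.2:c.2104T>C:p.C702R	0	27.2
2	USP40	chr2:234399901	G	GA	.	splicing	NM_001365479.1:c.2923dup:p.S975FfsTer65	0	27
2	TUBGCP6	chr22:50656236	G	A	rs138609686	missense	NM_020461.4:c.5389C>T:p.R1797C	0.0000649	26.6
2	AGAP3	chr7:150839000	T	G	.	missense	NM_001281300.2:c.827T>G:p.F276C	0	25.9
2	ITPR1	chr3:4706906	G	A	.	missense	NM_001099952.3:c.1639G>A:p.A547T	0	25.8
2	SPDL1	chr5:169028384	AG	A	.	splicing	NM_001329639.2:c.1426del:p.E476KfsTer19	0	25.7
2	RUNX1	chr21:36164605	A	C	.	missense	NM_001001890.3:c.1189T>G:p.S397A	0	25.5
2	TCF3	chr19:1646413	G	C	.	missense	NM_001136139.4:c.86C>G:p.P29R	0	25.2
2	NT5C1B-RDH14	chr2:18745234	C	T	rs147855687	missense	NM_001002006.3:c.1661G>A:p.R554H	0.000454	25
2	ABHD6	chr3:58279442	G	A	rs144907290	missense	NM_001320126.2:c.964G>A:p.D322N	0	24.9
2	EPHA2	chr1:16456073	C	T	.	missense	NM_001329090.2:c.2519G>A:p.R840Q	0	24.8
2	HSPA6	chr1:161494581	G	C	.	missense	NM_002155.5:c.133G>C:p.A45P	0	24.4
2	MYO16	chr13:109507831	C	T	.	missense	NM_001198950.3:c.1289C>T:p.T430M	0	23.8
2	SMC4	chr3:160135704	T	C	rs41272953	missense	NM_001002800.3:c.1631T>C:p.I544T	0.000115	23.5
2	PRKAR2A	chr3:48884770	T	G	.	missense	NM_001321982.2:c.260A>C:p.E87A	0	23.5
2	USP17L22	chr4:9270417	G	GA	.	splicing	NM_001256863.1:c.1073_1074insA:p.S358RfsTer20	0	23.3
2	ZYX	chr7:143079991	G	T	rs150223874	missense	NM_001010972.2:c.599G>T:p.W200L	0	23.1
2	ITFG1	chr16:47494745	T	G	rs376408976	splicing	NM_001305002.1:c.-132+281A>C	0	23.1
2	NYNRIN	chr14:24883816	T	C	.	missense	NM_025081.3:c.2861T>C:p.I954T	0	22.6
2	NIM1K	chr5:43280642	C	G	.	missense	NM_153361.4:c.1122C>G:p.N374K	0	22.3
2	DICER1	chr14:95570153	T	C	.	missense	NM_001271282.3:c.3580A>G:p.R1194G	0	21.8
2	NXNL1	chr19:17571431	G	A	rs377352923	missense	NM_138454.2:c.248C>T:p.T83M	0	21.5
2	TRPV6	chr7:142574988	G	T	rs139115329	missense	NM_018646.6:c.514C>A:p.L172M	0	21.2
2	ZNF320	chr19:53384145	G	C	.	missense	NM_001351773.1:c.1234C>G:p.L412V	0	21
2	ZNF320	chr19:53384768	A	G	rs144964547	missense	NM_001351773.1:c.611T>C:p.L204P	0.000907	20.7
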