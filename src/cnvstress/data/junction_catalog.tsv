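clone_id	genotype	aph_dose_uM	cnv_type	chrom	left_bp	right_bp	homology_len	homology_seq	insertion_seq
X6-5	Xrcc4_null	0.6	Deletion	chr1	68450738	68966178	1	A	-
X6-10	Xrcc4_null	0.6	Deletion	chr2	67650700	67818163	2	TT	-
X6-5	Xrcc4_null	0.6	Deletion	chr2	140718860	141009164	3	CAA	-
WT6-31	WT	0.6	Deletion	chr2	162172198	162232243	0	-	-
X6-11	Xrcc4_null	0.6	Deletion	chr3	156164457	156204161	2	TT	-
WT6-33	WT	0.6	Complex	chr4	153025685	153222760	1	G	-
WT6-33	WT	0.6	Complex	chr4	153025694	153222677	0	-	TG
WT6-33	WT	0.6	Complex	chr4	153222732	153025763	2	TG	-
WT6-33	WT	0.6	Complex	chr4	153222767	153222638	4	AACA	-
WT6-3	WT	0.6	Complex	chr5	5038414	5140617	3	CAT	-
WT6-3	WT	0.6	Complex	chr5	5141891	5167320	4	GGTA	-
X6-10	Xrcc4_null	0.6	Deletion	chr5	132199490	132455826	0	-	-
WT6-3	WT	0.6	Deletion	chr5	132226382	132474192	0	-	A
WT6-1	WT	0.6	Deletion	chr5	132476605	132681396	1	A	-
X6-37	Xrcc4_null	0.6	Deletion	chr5	132488580	132582758	2	CA	-
WT6-33	WT	0.6	Deletion	chr5	132621299	132650279	1	T	-
X6-11	Xrcc4_null	0.6	Complex	chr5	132624159	132850747	3	CAG	-
X6-11	Xrcc4_null	0.6	Complex	chr5	132850831	132844066	2	AC	-
X6-40	Xrcc4_null	0.6	Deletion	chr6	77628529	77694182	0	-	ATA
X6-6	Xrcc4_null	0.6	Complex	chr8	30060662	30079853	3	TCA	-
X6-6	Xrcc4_null	0.6	Complex	chr8	30080507	30102797	4	TCTG	-
X6-6	Xrcc4_null	0.6	Complex	chr8	30103083	30107692	5	AGCTC	-
WT6-1	WT	0.6	Deletion	chr9	28994436	29024833	2	GT	-
X6-7	Xrcc4_null	0.6	Duplication	chr9	69489187	68994934	2	CA	-
WT6-4	WT	0.6	Deletion	chr11	25829101	25853015	5	T(T/C)CTGC	-
X6-5	Xrcc4_null	0.6	Deletion	chr11	47093534	47349312	2	TC	-
X6-20	Xrcc4_null	0.6	Deletion	chr12	38642366	38735475	2	TT	-
WT6-32	WT	0.6	Deletion	chr12	80456477	80489599	3	GAG	-
WT6-14	WT	0.6	Deletion	chr14	23303767	23354878	0	-	-
X6-13	Xrcc4_null	0.6	Deletion	chr14	30009560	30339884	4	ACTA	-
X6-35	Xrcc4_null	0.6	Complex	chr16	49786986	49809344	2	GG	-
X6-35	Xrcc4_null	0.6	Complex	chr16	49809524	49805150	3	GCA	-
X6-4	Xrcc4_null	0.6	Deletion	chr16	66978951	67305221	1	C	-
WT6-14	WT	0.6	Deletion	chr16	97254626	97308282	1	C	-
X6-4	Xrcc4_null	0.6	Deletion	chr18	72162955	72298910	0	-	CA
X6-9	Xrcc4_null	0.6	Deletion	chrX	40273857	40335846	1	C	-
WT6-4	WT	0.6	Deletion	chrX	58904820	59057091	3	AGG	-
WT6-43	WT	0.6	Deletion	chrX	80613171	80738690	0	-	-
X6-6	Xrcc4_null	0.6	Deletion	chrX	84741276	84811809	0	-	-
X6-19	Xrcc4_null	0.6	Deletion	chrX	110651646	110711246	2	TT	-
X6-4	Xrcc4_null	0.6	Deletion	chrX	126700368	126786727	0	-	-
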