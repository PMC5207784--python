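# pgxpanel built-in panel definition, version 1
# variant rows define the 32 TaqMan assays (assay_id = rsid, except the
# locus probed in two allele contexts, split into rs5030865_T / rs5030865_A).
# allele rows define star alleles, one row per defining variant; alleles with
# no defining variant (*1, *5) have a single row with empty assay_id.
record	gene	assay_id	rsid	allele	ref_state	alt_state	change	effect	activity	score	structural
variant	CYP2C9	rs1799853	rs1799853		C	T	c. 430C>T	R144C			
variant	CYP2C9	rs1057910	rs1057910		A	C	c. 1075A>C	I359L			
variant	CYP2C9	rs56165452	rs56165452		T	C	c. 1076T>C	I359T			
variant	CYP2C9	rs28371686	rs28371686		C	G	c. 1080C>G	D360E			
variant	CYP2C9	rs9332131	rs9332131		A	delA	c. 818delA	273 Frameshift			
variant	CYP2C19	rs4244285	rs4244285		G	A	c. 681G>A	Splicing defect			
variant	CYP2C19	rs4986893	rs4986893		G	A	c. 636G>A	W212X			
variant	CYP2C19	rs28399504	rs28399504		A	G	c. 1A>G	M1V			
variant	CYP2C19	rs56337013	rs56337013		C	T	c. 1297C>T	R433W			
variant	CYP2C19	rs72552267	rs72552267		G	A	c. 395G>A	R132Q			
variant	CYP2C19	rs72558186	rs72558186		T	A	c. 819+2T>A	Splicing defect			
variant	CYP2C19	rs41291556	rs41291556		T	C	c. 358T>C	W120R			
variant	CYP2C19	rs28399507	rs28399507		G	A	c. 431G>A	R144H			
variant	CYP2C19	rs6413438	rs6413438		C	T	c. 680C>T	P227L			
variant	CYP2C19	rs12248560	rs12248560		C	T	c. -806C>T	Increased expression			
variant	CYP2D6	rs1080985	rs1080985		C	G	-1584C>G	Promoter			
variant	CYP2D6	rs16947	rs16947		C	T	2850C>T	R296C			
variant	CYP2D6	rs1135840	rs1135840		G	C	4180G>C	S486T			
variant	CYP2D6	rs35742686	rs35742686		A	delA	2549delA	259 Frameshift			
variant	CYP2D6	rs1065852	rs1065852		C	T	100C>T	P34S			
variant	CYP2D6	rs3892097	rs3892097		G	A	1846G>A	Splicing defect			
variant	CYP2D6	rs5030655	rs5030655		T	delT	1707delT	118 Frameshift			
variant	CYP2D6	rs5030867	rs5030867		A	C	2935A>C	H324P			
variant	CYP2D6	rs5030865_T	rs5030865		G	T	1758G>T	G169X			
variant	CYP2D6	rs5030865_A	rs5030865		G	A	1758G>A	G169R			
variant	CYP2D6	rs5030656	rs5030656		AAG	delAAG	2615_2617delAAG	K281del			
variant	CYP2D6	rs28371706	rs28371706		C	T	1023C>T	T107I			
variant	CYP2D6	rs59421388	rs59421388		G	A	3183G>A	V338M			
variant	CYP2D6	rs769258	rs769258		G	A	31G>A	V11M			
variant	CYP2D6	rs28371725	rs28371725		G	A	2988G>A	Splicing defect			
variant	CYP3A5	rs776746	rs776746		A	G	6986A>G	Splicing defect			
variant	VKORC1	rs9923231	rs9923231		G	A	c. -1639G>A	Promoter			
allele	CYP2C9			*1					normal	1.0	snv-defined
allele	CYP2C9	rs1799853		*2					decreased	0.5	snv-defined
allele	CYP2C9	rs1057910		*3					decreased	0.5	snv-defined
allele	CYP2C9	rs56165452		*4					decreased	0.5	snv-defined
allele	CYP2C9	rs28371686		*5					decreased	0.5	snv-defined
allele	CYP2C9	rs9332131		*6					none	0.0	snv-defined
allele	CYP2C19			*1					normal	1.0	snv-defined
allele	CYP2C19	rs4244285		*2					none	0.0	snv-defined
allele	CYP2C19	rs4986893		*3					none	0.0	snv-defined
allele	CYP2C19	rs28399504		*4					none	0.0	snv-defined
allele	CYP2C19	rs56337013		*5					none	0.0	snv-defined
allele	CYP2C19	rs72552267		*6					none	0.0	snv-defined
allele	CYP2C19	rs72558186		*7					none	0.0	snv-defined
allele	CYP2C19	rs41291556		*8					none	0.0	snv-defined
allele	CYP2C19	rs28399507		*9					decreased	0.5	snv-defined
allele	CYP2C19	rs6413438		*10					decreased	0.5	snv-defined
allele	CYP2C19	rs12248560		*17					increased		snv-defined
allele	CYP2D6			*1					normal	1.0	snv-defined
allele	CYP2D6	rs16947		*2					normal	1.0	snv-defined
allele	CYP2D6	rs1135840		*2					normal	1.0	snv-defined
allele	CYP2D6	rs1080985		*2A					normal	1.5	snv-defined
allele	CYP2D6	rs16947		*2A					normal	1.5	snv-defined
allele	CYP2D6	rs1135840		*2A					normal	1.5	snv-defined
allele	CYP2D6	rs35742686		*3					none	0.0	snv-defined
allele	CYP2D6	rs1065852		*4					none	0.0	snv-defined
allele	CYP2D6	rs3892097		*4					none	0.0	snv-defined
allele	CYP2D6	rs1135840		*4					none	0.0	snv-defined
allele	CYP2D6			*5					none	0.0	whole-gene-deletion
allele	CYP2D6	rs5030655		*6					none	0.0	snv-defined
allele	CYP2D6	rs5030867		*7					none	0.0	snv-defined
allele	CYP2D6	rs5030865_T		*8					none	0.0	snv-defined
allele	CYP2D6	rs16947		*8					none	0.0	snv-defined
allele	CYP2D6	rs1135840		*8					none	0.0	snv-defined
allele	CYP2D6	rs5030656		*9					decreased	0.5	snv-defined
allele	CYP2D6	rs1065852		*10					decreased	0.5	snv-defined
allele	CYP2D6	rs1135840		*10					decreased	0.5	snv-defined
allele	CYP2D6	rs5030865_A		*14					none	0.0	snv-defined
allele	CYP2D6	rs16947		*14					none	0.0	snv-defined
allele	CYP2D6	rs1135840		*14					none	0.0	snv-defined
allele	CYP2D6	rs28371706		*17					decreased	0.5	snv-defined
allele	CYP2D6	rs16947		*17					decreased	0.5	snv-defined
allele	CYP2D6	rs1135840		*17					decreased	0.5	snv-defined
allele	CYP2D6	rs16947		*29					decreased	0.5	snv-defined
allele	CYP2D6	rs59421388		*29					decreased	0.5	snv-defined
allele	CYP2D6	rs1135840		*29					decreased	0.5	snv-defined
allele	CYP2D6	rs769258		*35					normal	1.0	snv-defined
allele	CYP2D6	rs16947		*35					normal	1.0	snv-defined
allele	CYP2D6	rs1135840		*35					normal	1.0	snv-defined
allele	CYP2D6	rs1065852		*36					none	0.0	hybrid-exon9-conversion
allele	CYP2D6	rs1135840		*36					none	0.0	hybrid-exon9-conversion
allele	CYP2D6	rs16947		*41					decreased	0.5	snv-defined
allele	CYP2D6	rs28371725		*41					decreased	0.5	snv-defined
allele	CYP2D6	rs1135840		*41					decreased	0.5	snv-defined
allele	CYP3A5			*1					normal	1.0	snv-defined
allele	CYP3A5	rs776746		*3					none	0.0	snv-defined
allele	VKORC1			*1					normal		snv-defined
allele	VKORC1	rs9923231		*2					decreased		snv-defined
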