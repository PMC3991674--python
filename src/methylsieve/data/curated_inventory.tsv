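accession	symbol	description	category	location	position	residue	degrees	flags	alt_positions	sc_methyl	sc_total	positioning_3d
AT1G56190.1	PGK2	Phosphoglycerate kinase family protein	Photosynthesis. Calvin cycle	stroma	329	K	me2					Surface exposed
AT1G67090.1	RBCS1A	Rubisco small subunit 1A	Photosynthesis. Calvin cycle	stroma	66	K	me1/2					Surface exposed
AT1G67090.1	RBCS1A	Rubisco small subunit 1A	Photosynthesis. Calvin cycle	stroma	140	K	me2		147			Surface exposed
AT1G67090.1	RBCS1A	Rubisco small subunit 1A	Photosynthesis. Calvin cycle	stroma	146	K	me1/2					Surface exposed
AT2G21330.1	FBA1	Fructose-bisphosphate aldolase 1	Photosynthesis. Calvin cycle	stroma	395	K	me3	c				Protruding
AT2G39730.1	RCA	Rubisco activase	Photosynthesis. Calvin cycle	stroma	204	K	me1/3					Surface exposed
AT3G04790.1	PRI	Ribose 5-phosphate isomerase	Photosynthesis. Calvin cycle	stroma	200	K	me1					Protruding
AT3G12780.1	PGK1	Phosphoglycerate kinase 1	Photosynthesis. Calvin cycle	stroma	424	K	me1					Protruding
ATCG00490.1	RBCL	Rubisco large subunit	Photosynthesis. Calvin cycle	stroma	32	K	me2/3	a				Protruding
ATCG00490.1	RBCL	Rubisco large subunit	Photosynthesis. Calvin cycle	stroma	79	R	me2					Protruding
ATCG00490.1	RBCL	Rubisco large subunit	Photosynthesis. Calvin cycle	stroma	201	K	me1/2/3					Buried
ATCG00490.1	RBCL	Rubisco large subunit	Photosynthesis. Calvin cycle	stroma	236	K	me1/3	a				Buried
ATCG00490.1	RBCL	Rubisco large subunit	Photosynthesis. Calvin cycle	stroma	339	R	me1/2					Surface exposed
ATCG00490.1	RBCL	Rubisco large subunit	Photosynthesis. Calvin cycle	stroma	356	K	me2					Protruding
AT1G32990.1	PRPL11	Plastid ribosomal protein L11	Protein synthesis	stroma	109	K	me3	c				Protruding
AT1G79530.1	GAPCP1	Glyceraldehyde-3-phosphate dehydrogenase of plastid 1	Glycolysis	stroma	407	R	me1					Buried
AT3G11630.1	PrxA	2-Cys peroxiredoxin	Redox	stroma	202	K	me1/2/3					Surface exposed
AT5G09650.1	PPA1	Pyrophosphate phospho-hydrolase 1	Nucleotide metabolism	stroma	118	K	me1					Buried
AT2G20260.1	PSAE-2	Photosystem I subunit E-2	Photosynthesis. Light reaction	thylakoid	145	K	me1					Protruding
AT3G50820.1	PSBO-2	Photosystem II subunit O-2	Photosynthesis. Light reaction	thylakoid	292	K	me1					Surface exposed
AT4G17600.1	LIL3:1	Chlorophyll A-B binding family protein	Photosynthesis. Light reaction	thylakoid	101	K	me1					NA
AT4G32260.1	ATPG	ATP synthase beta chain	Photosynthesis. Light reaction	thylakoid	129	K	me1/3					NA
ATCG00120.1	ATPA	ATP synthase subunit alpha	Photosynthesis. Light reaction	thylakoid	141	R	me1					Surface exposed
ATCG00480.1	ATPB	ATP synthase subunit beta	Photosynthesis. Light reaction	thylakoid	52	R	me1/2			2	45	Surface exposed
ATCG00480.1	ATPB	ATP synthase subunit beta	Photosynthesis. Light reaction	thylakoid	447	K	me1/2					Surface exposed
AT1G03630.2	PORC	Protochlorophyllide reductase C	Tetrapyrrole synthesis	thylakoid	87	K	me2					Protruding
AT1G06950.1	TIC110	Translocon at the inner envelope membrane of chloroplasts 110	Protein targeting	envelope	946	K	me2					NA
AT3G18890.1	TIC62	Translocon at the inner envelope membrane of chloroplasts 62	Protein targeting	envelope	79	K	me3	a				NA
AT4G13010.1	ceQORH	Quinone-oxidoreductase homolog	Miscellaneous enzyme	envelope	119	R	me2					Surface exposed
AT5G42480.1	ARC6	Protein Accumulation and Replication of Chloroplast 6	Cell. Division	envelope	516	R	me1					NA
AT5G46110.3	TPT	Triose phosphate/phosphate translocator	Transport	envelope	96	K	me1					NA
AT1G07920.1	eEF-1A	Elongation factor 1-alpha	Protein synthesis	cytosol	44	K	me1/2					Protruding
AT1G07920.1	eEF-1A	Elongation factor 1-alpha	Protein synthesis	cytosol	187	K	me3	c				Protruding
AT1G15780.1	MED15A	Mediator of RNA polymerase II transcription subunit 15a	Not assigned	nucleus	85	K	me1					NA
AT2G33090.1		Transcription elongation factor (TFIIS) family protein	Not assigned	nucleus	79	K	me3	c				NA
AT3G48250.1	BIR6	Pentatricopeptide repeat-containing protein	Not assigned	mitochondrion	394	K	me1					Surface exposed
AT5G39410.1	SDH	Saccharopine dehydrogenase	Not assigned	mitochondrion	6	K	me3	a				NA
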