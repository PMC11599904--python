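group	chrom	pos	ref	alt	gene	region_detail	impact	frequency
INDG-LLA	chr4	99344935	G	A	ADH1C	non synonymous coding	Moderate	0.1
INDG-LLA	chr3	41239384	A	G	CTNNB1	intron	Modifier	0.1
INDG-LLA	chr5	177093290	G	C	FGFR4	non synonymous coding	Moderate	0.1
INDG-LLA	chr5	177097403	G	GC	FGFR4	intron	Modifier	0.1
INDG-LLA	chr5	177097408	T	G	FGFR4	intron	Modifier	0.25
INDG-LLA	chr5	177097412	A	C	FGFR4	intron	Modifier	0.167
INDG-LLA	chr5	177097416	A	C	FGFR4	intron	Modifier	0.1
INDG-LLA	chr5	177097419	A	C	FGFR4	intron	Modifier	0.1
INDG-LLA	chr5	177097422	T	A	FGFR4	intron	Modifier	0.125
INDG-NLLA	chr5	163473551	G	T	HMMR	stop gained	High	0.012
INDG-NLLA	chr12	117330580	C	A	NOS1	non synonymous coding	Moderate	0.012
INDG-NLLA	chr3	41224558	C	T	CTNNB1	non synonymous coding	Moderate	0.018
INDG-NLLA	chr3	41239384	A	G	CTNNB1	intron	Modifier	0.009
INDG-NLLA	chr20	57265970	C	A	BMP7	synonymous coding	Low	0.009
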