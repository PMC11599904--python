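dimension	category	count	percent
mutation_type	SNV	226	89.3
mutation_type	INDEL	27	10.7
region	3'UTR	9	3.6
region	5'UTR	7	2.8
region	exon/CDS	79	31.2
region	intragenic	8	3.2
region	intronic	134	52.9
region	other	16	6.3
consequence	intragenic	8	3.2
consequence	intronic	134	52.9
consequence	next protein	2	0.8
consequence	non synonymous coding	38	15.0
consequence	non synonymous coding + splice site region	1	0.4
consequence	protein structural interaction locus	5	1.9
consequence	splice site region + intron	8	3.2
consequence	synonymous coding	40	15.8
consequence	stop gained	1	0.4
consequence	3'UTR	9	3.6
consequence	5'UTR	7	2.8
impact	High	6	2.4
impact	Moderate	39	15.4
impact	Modifier	158	62.4
impact	Low	50	19.8
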