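pop1	pop2	r2	f	p
IND-NLLA	IND-LLA	0.058	3.838	0.006
IND-NLLA	AFR	0.118	96.375	0.006
IND-NLLA	AMR	0.057	24.625	0.006
IND-NLLA	EAS	0.093	57.700	0.006
IND-NLLA	EUR	0.079	48.208	0.006
IND-NLLA	SAS	0.060	34.547	0.006
IND-LLA	AFR	0.007	4.913	0.055
IND-LLA	AMR	0.003	1.046	0.319
IND-LLA	EAS	0.004	2.167	0.309
IND-LLA	EUR	0.005	2.322	0.309
IND-LLA	SAS	0.003	1.560	0.319
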