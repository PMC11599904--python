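gene	gene_text	variant	impact	p_IND-LLA	sign_IND-LLA	p_AFR	sign_AFR	p_AMR	sign_AMR	p_EAS	sign_EAS	p_EUR	sign_EUR	p_SAS	sign_SAS
ABCB1	ABCB1	rs2032582	Moderate	2.320e-35	-	8.933e-51	-	8.429e-22	-	8.367e-18	-	2.938e-22	-	2.817e-12	-
ADH1C	ADH1C	rs1693482	Moderate	1.161e-9	+	6.505e-3	+	0.974	-	8.127e-4	+	3.072e-2	-	0.974	-
ADH1C	ADH1C	rs35719513	Moderate	1.206e-6	+	1.206e-6	+	1.406e-2	+	1.206e-6	+	1.206e-6	+	1.206e-6	+
FGFR4	FGFR4	rs1966265	Moderate	0.126	+	1.211e-20	+	2.313e-5	+	0.256	+	3.531e-9	+	3.531e-9	+
FGFR4	FGFR4	rs351855	Moderate	1.540e-6	-	4.025e-4	-	3.699e-16	-	5.577e-17	-	1.718e-10	-	1.202e-12	-
FGFR4	FGFR4	rs376618	Moderate	0.325	-	2.413e-10	+	1.016e-2	+	0.325	-	1.682e-6	+	2.884e-2	+
GSTA1	GSTA1	rs1051775	High	5.466e-4	-	0.264	-	5.466e-4	-	0.052	-	6.629e-12	-	7.095e-9	-
HMMR	HMMR	rs299284	Moderate	1.835e-2	-	3.135e-2	-	0.235	-	1	+	3.221e-3	-	1.835e-2	-
HMMR	HMMR	rs299295	Moderate	0.433	-	1.191e-5	-	3.376e-2	-	1	-	2.389e-4	-	7.389e-5	-
NOS3	NOS1	rs11068428	Moderate	2.677e-15	+	6.645e-21	+	1.050e-3	+	2.365e-7	+	2.007e-14	+	3.708e-13	+
PNPLA3	PNPLA3	rs2076213	Moderate	1	-	1.064e-6	+	4.548e-2	+	4.937e-8	+	2.218e-4	+	2.218e-4	+
PNPLA3	PNPLA3	rs2294918	Moderate	3.279e-3	+	0.112	+	5.412e-3	+	2.239e-2	+	7.285e-10	+	4.072e-5	+
PNPLA3	PNPLA3	rs738409	Moderate	0.438	+	2.692e-16	+	0.244	+	4.072e-5	+	7.274e-11	+	2.777e-11	+
SERPINA6	SERPINA6	rs2228541	Moderate	0.295	+	3.591e-20	+	7.183e-6	+	0.874	+	1.903e-17	+	3.490e-9	+
SHMT1	SHMT1	rs1979277	Moderate	7.675e-3	-	1.337e-3	-	2.504e-2	-	0.112	+	5.049e-3	-	1	-
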