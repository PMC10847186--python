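panel	class	OER_<10	OER_10-20	OER_20-30	OER_30-40	OER_40-50	OER_50-60	OER_>30	OER_>60
Neu_c3_CST7	specific	96.88	0	0	0	0	0	3.12	3.12
Tnf_Neu	specific	96.88	0	0	0	0	0	3.12	3.12
Rps19_Neu	specific	96.88	0	0	0	0	0	3.12	3.12
RSAD2_Neu	specific	96.88	0	0	0	0	0	3.12	3.12
CSF1_Neu	specific	96.88	0	0	0	0	0	3.12	3.12
Cd34_mNeu	specific	96.88	0	0	0	0	0	3.12	3.12
Ltf_mNeu	specific	96.88	0	0	0	0	0	3.12	3.12
ELL2/Marco_Neu	specific	90.62	3.12	0	0	0	0	6.25	6.25
CD74_Neu	specific	96.88	0	0	0	0	0	3.12	3.12
IFIT1_Neu	specific	96.88	0	0	0	0	0	3.12	3.12
Neu_c1_IL1B	associate	40.62	15.62	21.88	9.38	3.12	3.12	21.88	6.25
Neu_c5_GSTP1(high)OASL(low)	associate	81.25	0	0	3.12	3.12	3.12	18.75	9.38
S100A12/Pabpc1_Neu	associate	90.62	0	0	0	0	0	9.38	9.38
Neu_c2_CXCR4(low)	reference	25	18.75	3.12	0	3.12	21.88	53.12	28.12
IFNactive neutrophils	reference	81.25	0	0	0	0	0	15.62	15.62
IL-7R + neutrophils	reference	84.38	0	0	0	3.12	0	15.62	12.5
Circulating neutrophils	reference	62.5	0	0	0	0	12.5	37.5	25
Naive neutrophils	reference	18.75	0	0	3.12	6.25	34.38	81.25	37.5
IFN_experienced neutrophils	reference	84.38	0	0	0	0	0	15.62	15.62
Isg15_Neu	reference	84.38	0	0	0	0	0	15.62	15.62
Canonical_Neu	reference	37.5	3.12	0	6.25	0	6.25	59.38	46.88
BALF_Neu	reference	50	0	3.12	3.12	3.12	0	46.88	40.62
Bladder_Neu	reference	56.25	3.12	3.12	0	0	6.25	37.5	31.25
IFITM2_Neu	reference	50	0	0	3.12	3.12	0	50	43.75
Anxa1_Neu	reference	71.88	0	3.12	0	3.12	0	25	21.88
Classical_Neu	reference	37.5	3.12	3.12	15.62	15.62	6.25	56.25	18.75
Lgals1_mNeu	reference	50	6.25	0	3.12	0	3.12	43.75	37.5
ISG15/Ifit3_Neu	reference	84.38	0	0	0	0	0	15.62	15.62
TXNIP/Gm2a_Neu	reference	37.5	9.38	6.25	12.5	9.38	9.38	46.88	15.62
PTGS2/Actg1_Neu	reference	75	6.25	3.12	0	3.12	0	15.62	12.5
SPP1_Neu	reference	75	0	0	0	0	0	21.88	21.88
CCL4_Neu	reference	81.25	0	0	3.12	0	0	18.75	15.62
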