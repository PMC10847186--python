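Neu_c3_CST7	SYNTHETIC placeholder gene list, not the published panel	CST7	PLAC01	PLAC02
Tnf_Neu	SYNTHETIC placeholder gene list, not the published panel	TNF	PLAC03	PLAC04
Rps19_Neu	SYNTHETIC placeholder gene list, not the published panel	RPS19	PLAC05
RSAD2_Neu	SYNTHETIC placeholder gene list, not the published panel	RSAD2	PLAC06
CSF1_Neu	SYNTHETIC placeholder gene list, not the published panel	CSF1	PLAC07
Cd34_mNeu	SYNTHETIC placeholder gene list, not the published panel	CD34	PLAC08
Ltf_mNeu	SYNTHETIC placeholder gene list, not the published panel	LTF	PLAC09
ELL2/Marco_Neu	SYNTHETIC placeholder gene list, not the published panel	ELL2	MARCO
CD74_Neu	SYNTHETIC placeholder gene list, not the published panel	CD74	PLAC10
IFIT1_Neu	SYNTHETIC placeholder gene list, not the published panel	IFIT1	PLAC11
Neu_c1_IL1B	SYNTHETIC placeholder gene list, not the published panel	IL1B	CXCL8	PLAC12
Neu_c5_GSTP1(high)OASL(low)	SYNTHETIC placeholder gene list, not the published panel	GSTP1(high)	OASL(low)	PLAC13
S100A12/Pabpc1_Neu	SYNTHETIC placeholder gene list, not the published panel	S100A12	PABPC1
Neu_c2_CXCR4(low)	SYNTHETIC placeholder gene list, not the published panel	CXCR4(low)	PLAC14	PLAC15
IFNactive neutrophils	SYNTHETIC placeholder gene list, not the published panel	IFIT3	PLAC16
IL-7R + neutrophils	SYNTHETIC placeholder gene list, not the published panel	IL7R	PLAC17
Circulating neutrophils	SYNTHETIC placeholder gene list, not the published panel	FCGR3B	PLAC18
Naive neutrophils	SYNTHETIC placeholder gene list, not the published panel	SELL	PLAC19
IFN_experienced neutrophils	SYNTHETIC placeholder gene list, not the published panel	IFITM1	PLAC20
Isg15_Neu	SYNTHETIC placeholder gene list, not the published panel	ISG15	PLAC21
Canonical_Neu	SYNTHETIC placeholder gene list, not the published panel	CSF3R	S100A8	S100A9
BALF_Neu	SYNTHETIC placeholder gene list, not the published panel	PLAC22	PLAC23
Bladder_Neu	SYNTHETIC placeholder gene list, not the published panel	PLAC24	PLAC25
IFITM2_Neu	SYNTHETIC placeholder gene list, not the published panel	IFITM2	PLAC26
Anxa1_Neu	SYNTHETIC placeholder gene list, not the published panel	ANXA1	PLAC27
Classical_Neu	SYNTHETIC placeholder gene list, not the published panel	PLAC28	PLAC29
Lgals1_mNeu	SYNTHETIC placeholder gene list, not the published panel	LGALS1	PLAC30
ISG15/Ifit3_Neu	SYNTHETIC placeholder gene list, not the published panel	ISG15	IFIT3	PLAC31
TXNIP/Gm2a_Neu	SYNTHETIC placeholder gene list, not the published panel	TXNIP	GM2A
PTGS2/Actg1_Neu	SYNTHETIC placeholder gene list, not the published panel	PTGS2	ACTG1
SPP1_Neu	SYNTHETIC placeholder gene list, not the published panel	SPP1	PLAC32
CCL4_Neu	SYNTHETIC placeholder gene list, not the published panel	CCL4	PLAC33
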