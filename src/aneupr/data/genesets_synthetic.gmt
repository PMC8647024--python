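UPR_58	synthetic stand-in for the 58-gene UPR set	HSPA5	CXXC1	GSK3A	SERP1	PDIA6	FKBP14	SHC1	ATF4	DDIT3	XBP1	ERN1	EIF2S1	EIF2AK3	ATF6	IGFBP1	SRPRB	PREB	WIPI1	KDELR3	CUL7	GOSR2	SYVN1	YIF1A	PLA2G4B	ASNS	SSR1	ATF6B	CREB3	CREB3L1	CREB3L2	HERPUD1	DNAJB9	DNAJC3	EDEM1	SEC61A1	SRPRA	PPP1R15A	NFYA	NFYB	NFYC	ERO1A	CALR	CANX	PDIA3	HYOU1	DDOST	EXTL3	ADD1	ACADVL	MBTPS1	MBTPS2	ARFGAP1	KLHDC3	TATDN2	ZBTB17	TSPYL2	CEBPB	DCTN1
PERK	synthetic stand-in for the PERK branch set	EIF2AK3	EIF2S1	ATF4	DDIT3	PPP1R15A	ASNS	CEBPB	HERPUD1	IGFBP1	SHC1	NFYA	GSK3A
XBP1S	synthetic stand-in for the XBP1s branch set	XBP1	ERN1	HSPA5	PDIA6	DNAJB9	DNAJC3	EDEM1	SERP1	SEC61A1	SSR1	SRPRA	SRPRB	KDELR3	GOSR2	SYVN1	WIPI1	YIF1A	FKBP14
ATF6	synthetic stand-in for the ATF6 branch set	ATF6	ATF6B	HSPA5	CALR	CANX	HERPUD1	MBTPS1	MBTPS2	CREB3	CREB3L1	CREB3L2	XBP1
RIDD_33	synthetic stand-in for the 33 RIDD target genes	BLOC1S1	SCARA3	PDGFRB	PER1	COL6A1	ANGPTL3	HGSNAT	PMP22	TAPBP	ITGB2	CD59	SPARC	AMIGO2	DGAT2	SERPINA1	CTSB	LAMB1	COL4A1	FN1	THBS1	TIMP1	MMP2	SDC4	GAS6	PLOD2	LOXL2	P4HB	TXNDC5	ERP29	SEL1L	DNAJC10	EDEM3	OS9
TP53_REPRESSED_10	10 P53 downstream repressed genes	CCNB1	PLK1	EED	CDK1	EZH2	CCNB2	E2F3	MYBL2	FOXM1	E2F2
CYT	cytolytic activity genes	GZMA	PRF1
CONTROL_OLFACTION	non-oncogenic control pathway	OR1A1	OR2B6	OR5AN1	OR7C1	OR51E2	OR10A4	OR4D6	OR6C74	OR8B8	OR2T1	RTP1	RTP2	REEP1	GNAL	ADCY3	CNGA2	CNGA4	CNGB1	OMP	UGT2A1
CONTROL_CARDIAC_CONDUCTION	non-oncogenic control pathway	SCN5A	KCNQ1	KCNH2	KCNE1	KCNE2	KCNJ2	CACNA1C	CACNA1D	HCN4	HCN1	GJA1	GJA5	RYR2	ATP1A1	ATP1B1	SLC8A1	CAMK2D	CASQ2	PLN	TRDN
CONTROL_PHOTOTRANSDUCTION	non-oncogenic control pathway	RHO	GNAT1	GNB1	GNGT1	PDE6A	PDE6B	PDE6G	CNGA1	CNGB3	GRK1	SAG	RCVRN	GUCA1A	GUCY2D	RGS9	OPN1SW	OPN1MW	ARR3	METAP2	FNTA
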