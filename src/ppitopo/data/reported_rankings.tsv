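gene_by_degree	degree	gene_by_closeness	closeness	gene_by_betweenness	betweenness
TP53	113	EGFR	0.75409836	TSPO	0.04809981
TSPO	93	MAPK14	0.75	TP53	0.03881821
AKT1	90	CDKN1B	0.75	AKT1	0.01744922
EGFR	79	CDK4	0.73684211	EGFR	0.01611723
CDH1	66	TSPO	0.69767442	VEGFA	0.01249361
CCND1	61	STAT3	0.6875	IL6	0.00829916
VEGFA	60	IL6	0.67741935	MTOR	0.00784171
IL6	60	CD68	0.66666667	CDH1	0.00782314
STAT3	56	CHAF1A	0.66666667	CXCR2	0.00712798
FGF2	53	OAZ1	0.66666667	SMAD4	0.00692481
MTOR	49	EGR1	0.64705882	XRCC3	0.00531283
MAPK14	49	FGF2	0.63829787	MET	0.00516178
CDKN2A	47	BIRC5	0.63513514	UBB	0.00501709
TGFB1	47	MMP1	0.63218391	PARP1	0.00451757
KDR	42	RAF1	0.63157895	GJA1	0.00447296
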