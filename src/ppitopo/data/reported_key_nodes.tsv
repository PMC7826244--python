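gene	degree	betweenness
TSPO	93	0.04809981
TP53	113	0.03881821
AKT1	90	0.01744922
EGFR	79	0.01611723
VEGFA	60	0.01249361
IL6	60	0.00829916
MTOR	49	0.00784171
CDH1	66	0.00782314
CXCR2	17	0.00712798
SMAD4	39	0.00692481
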