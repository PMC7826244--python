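ABCA1
ABCE1
ADAM17
AKT1
ALCAM
ANG
ANKRD6
ANXA1
APC2
ATP2A2
ATP2A3
AURKA
AXIN2
BECN1
BIRC5
BNIP2
BRCA2
CA9
CALML3
CASP7
CCL20
CCL5
CCND1
CCND2
CCNH
CCR4
CD14
CD207
CD44
CD68
CDH1
CDK4
CDKN1B
CDKN1C
CDKN2A
CHAF1A
CHAF1B
COL17A1
CP
CSNK1E
CXCL2
CXCL3
CXCR1
CXCR2
CXCR7
CYP1A1
CYP26B1
CYP2E1
DCN
DCTN6
DDX3X
DIABLO
DICER1
DNAH8
DNAJA3
DNMT3B
DPAGT1
DSC2
DSG1
DSG2
DUSP1
E2F1
EDNRB
EGFR
EGR1
ELAVL3
ENG
ERCC2
FADD
FAM48A
FGF2
FHIT
GAD1
GDNF
GHRL
GJA1
GPX1
GRIK2
GRM5
GSK3A
GSTM1
GSTO1
GSTP1
HBA1
HMGA2
HMGB1
HNRNPD
HOXA10
HOXA9
HPSE
HSPA5
HSPG2
ICAM1
ICAM3
IL1F10
IL6
ITGB2
ITGB4
KDR
KLF4
KLF8
KRT19
LAMC2
LBX1
LCN2
LDHA
LIN28B
MAPK14
MET
MGMT
MMP1
MMP7
MOK
MSI1
MT1A
MT3
MTA1
MTHFR
MTOR
MVD
MYCBP
NAT2
NES
NNMT
NRP1
OAZ1
OPRM1
ORAOVA1
PABPN1
PARP1
PDK1
PDPN
PGK1
PHLDA1
PIK3CA
PIM1
POFUT1
POLG2
POLRMT
PRDM14
PREX2
PRKAB1
PROM1
PROX1
PTGS2
PTMA
PTPN11
PTPRJ
PTPRR
PTPRZ1
RAF1
RASGRP3
REST
RPL30
RPL37A
RPS17
S100A1
S100A2
S100A4
S100A7
S100A9
S100B
S100P
SEMA3C
SF3B3
SIRT1
SIRT3
SLC2A1
SLPI
SMAD2
SMAD4
SMC2
SMURF1
SOD2
SOX2
SRF
ST14
STAG2
STAT3
TERT
TFRC
TGFB1
TGFBR1
TGFBR2
TIMP3
TIMP4
TLR2
TLR3
TLR4
TNFRSF11B
TNFSF10
TP53
TP73
TSPO
TWIST1
TXNRD2
UBB
VEGFA
WIF1
WNT2B
WWP1
XRCC1
XRCC2
XRCC3
XRCC4
YES1
ZBTB7A
VEGF
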