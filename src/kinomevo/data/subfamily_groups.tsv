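subfamily	group
RLK-Pelle_DLSV	RLK
RLK-Pelle_LRR-XI-1	RLK
RLK-Pelle_LRR-XII-1	RLK
RLK-Pelle_LRR-III	RLK
RLK-Pelle_LysM	RLK
RLK-Pelle_WAK	RLK
RLK-Pelle_RLCK-VIIa-2	RLK
RLK-Pelle_RLCK-IXa	RLK
RLK-Pelle_LRK10L-2	RLK
RLK-Pelle_CrRLK1L-1	RLK
RLK-Pelle_SD-2b	RLK
AGC_NDR	AGC
AGC_RSK-2	AGC
AGC-Pl	AGC
CAMK_CDPK	CAMK
CAMK_AMPK	CAMK
CAMK_CAMKL-CHK1	CAMK
CAMK_OST1L	CAMK
CMGC_MAPK	CMGC
CMGC_GSK	CMGC
CMGC_CDK-CDK7	CMGC
CMGC_CDK-CRK7-CDK9	CMGC
STE_STE11	STE
STE_STE7	STE
STE_STE20	STE
TKL-Pl-3	TKL
TKL-Pl-4	TKL
TKL_IRAK	TKL
WNK_NRBP	other
CK1_CK1	other
CK1_CK1-Pl	other
Aur	other
ULK_ULK4	other
NEK	other
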