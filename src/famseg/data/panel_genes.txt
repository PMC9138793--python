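BRCA1
BRCA2
CDH1
CHEK2
PTEN
STK11
TP53
ATM
BARD1
BRIP1
CDKN2A
MRE11A
NBN
PALB2
RAD50
RAD51C
RAD51D
ATR
BABAM1
BAP1
BCCIP
BLM
BRAP
BRCC3
BRE
C17orf70
C19orf40
CDK4
FAM175A
FAN1
FANCA
FANCB
FANCC
FANCD2
FANCE
FANCF
FANCG
FANCI
FANCL
FANCM
HUS1
KLLN
MDC1
RAD1
RAD17
RAD51
RAD51B
RAD52
RAD54L
RAD9A
RBBP8
RMI1
RMI2
SDHB
SDHD
SLX4
TOP3A
TOPBP1
TP53BP1
UIMC1
XRCC2
XRCC3
XRCC4
ZNF350
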