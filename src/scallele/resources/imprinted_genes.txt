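# Curated monoallelically expressed (imprinted) genes excluded from the
# allelic model; one symbol per line. Edit or replace via --imprinted.
H19
IGF2
IGF2-AS
KCNQ1
KCNQ1OT1
CDKN1C
PHLDA2
SLC22A18
MEG3
MEG8
RTL1
DLK1
DIO3
SNRPN
SNURF
NDN
MKRN3
MAGEL2
UBE3A
PEG3
ZIM2
PEG10
SGCE
MEST
PLAGL1
HYMAI
GNAS
GNAS-AS1
NAP1L5
NNAT
BLCAP
DIRAS3
ZDBF2
GRB10
INPP5F
RB1
ATP10A
OSBPL5
ZNF597
PEG13
KCNK9
L3MBTL1
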