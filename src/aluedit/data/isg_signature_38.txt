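ADAR
BST2
DDX58
DDX60
EPSTI1
ETV7
GBP1
GBP4
HERC5
HERC6
IFI27
IFI44
IFI44L
IFI6
IFIH1
IFIT1
IFIT3
IFITM3
IRF7
IRF9
ISG15
LY6E
MX1
MX2
OAS1
OAS2
OAS3
OASL
PLSCR1
RSAD2
SAMD9
SAMD9L
SIGLEC1
SOCS1
STAT1
STAT2
USP18
XAF1
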