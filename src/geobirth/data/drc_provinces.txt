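# Pre-2015 DRC province contiguity (11 provinces).
# KIN Kinshasa, BCG Bas-Congo, BDD Bandundu, EQT Equateur, ORI Orientale,
# NKV Nord-Kivu, MNM Maniema, SKV Sud-Kivu, KTG Katanga,
# KOC Kasai-Occidental, KOR Kasai-Oriental.
nodes: KIN BCG BDD EQT ORI NKV MNM SKV KTG KOC KOR
KIN BCG
KIN BDD
BCG BDD
BDD EQT
BDD KOC
EQT ORI
EQT KOC
EQT KOR
ORI NKV
ORI MNM
ORI KOR
NKV SKV
NKV MNM
SKV MNM
SKV KTG
MNM KTG
MNM KOR
KTG KOR
KTG KOC
KOR KOC
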