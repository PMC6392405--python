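name	recognition
EcoRI	GAATTC
BamHI	GGATCC
HindIII	AAGCTT
PstI	CTGCAG
SalI	GTCGAC
XhoI	CTCGAG
KpnI	GGTACC
SacI	GAGCTC
XbaI	TCTAGA
SmaI	CCCGGG
NcoI	CCATGG
SphI	GCATGC
NdeI	CATATG
NheI	GCTAGC
SpeI	ACTAGT
ApoI	RAATTY
StyI	CCWWGG
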