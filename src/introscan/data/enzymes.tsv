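name	recognition	cut_offset
AvaI	CYCGRG	1
EcoRI	GAATTC	1
HindIII	AAGCTT	1
BamHI	GGATCC	1
TaqI	TCGA	1
AluI	AGCT	2
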