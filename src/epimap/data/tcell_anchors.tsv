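# High-frequency (>70%) HLA-DR class II anchor motif start residues
# (9-mer convention) in profilin sequences of five plant species.
# Empty cell = motif not found at high frequency in that species.
# Columns: anchor label per species; one row per homologous anchor.
olea_europaea	betula_pendula	corylus_avellana	phleum_pratense	zea_mays
V29	V28	V28		V26
	W35	W35
	F41
F45	F44		F42	F39
I53
				F59
L68			M65	L65
			F66
L70	L69	L69	V67	L67
M76	M75	M75	M73	M73
I86			I83	I83
I95	I94	I94	I92
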