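# Monoclonal-antibody-defined linear B-cell epitopes of plant profilin
# (characterised on sunflower profilin Hel a 2 with overlapping synthetic
# peptides). Localisation on any given profilin is by sequence match; the
# original Hel a 2 coordinates do not transfer across species.
label	kind	sequence
10A4	bcell	MSWQAYV
5F2	bcell	AQSAKFPQFKPEEM
9A7	bcell	GQAMIMGIYD
9G4	bcell	YDEPVAPG
3H8	bcell	ERLGDY
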