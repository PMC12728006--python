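# Complementary mechanisms: effectors reverted exclusively by one of the two
# drugs (vedolizumab = drug A, JAK inhibitors = drug B) and maintained in the
# combination. Columns: protein, motives (semicolon list), per-motive disease
# signs, and the modulation called for each treatment (down / up / none).
protein	motives	disease_signs	mod_a	mod_b	mod_combo
ITGA4	3	up	down	none	down
ITGB7	3	up	down	none	down
PDGFB	4	up	down	none	down
NFKB2	1;3;4	up;up;up	down	none	down
IL5	4	up	down	none	down
IGF2	4	up	down	up	down
MMP9	4	up	down	up	down
IL6	4	up	down	up	down
CLDN2	1	up	down	up	down
TLR4	3	down	down	up	up
IL13	4	down	down	up	up
MICB	3	up	none	down	down
TGFBR2	4	up	none	down	down
WNT1	1;4	down;down	none	up	up
PPARG	1	down	none	up	up
IL22	1;3	down;down	none	up	up
EGF	4	up	up	down	down
COL1A1	4	up	up	down	down
MSH2	4	up	up	down	down
COL1A2	4	up	up	down	down
CLDN1	1	down	up	none	up
OCLN	1	down	up	down	up
TJP1	1	down	up	down	up
CLDN3	1	down	up	down	up
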