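# Convergent effectors: reverted by vedolizumab (drug A) and JAK inhibitors
# (drug B) independently, and at least as strongly by their combination.
# NOTE: the source running text lists this protein set once with the spelling
# "PAMK3"; the table body spells it MAPK3, which is the recognised gene symbol
# and is what this fixture records. The discrepancy is flagged, not resolved.
protein	motives	disease_signs	mod_a	mod_b	mod_combo
CCR9	3	up	down	down	down
CDH1	1	down	up	up	up
FASLG	3	up	down	down	down
IFNG	1;3;4	up;up;down	down	down	down
MAPK1	4	up	down	down	down
MAPK3	4	up	down	down	down
MMP1	1;4	up;down	down	down	down
NFKB1	1;3;4	up;up;up	down	down	down
PLA2G1B	1	up	down	down	down
TCF4	1;4	down;up	down	down	down
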