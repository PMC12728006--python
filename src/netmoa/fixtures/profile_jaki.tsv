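# Pan-JAK inhibitor profile: all four Janus kinase family members inhibited.
protein	effect_sign	is_pseudotarget
JAK1	-1	false
JAK2	-1	false
JAK3	-1	false
TYK2	-1	false
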