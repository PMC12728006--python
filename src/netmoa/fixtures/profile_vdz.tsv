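# Vedolizumab target profile: the antibody blocks the alpha4/beta7 integrin
# heterodimer. MADCAM1 is a pseudotarget: the drug does not bind it, but
# clamping it inhibited represents the blocked integrin-MAdCAM-1 interaction.
protein	effect_sign	is_pseudotarget
ITGA4	-1	false
ITGB7	-1	false
MADCAM1	-1	true
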