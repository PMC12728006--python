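# Vedolizumab bioflags: downstream proteins the literature reports as
# modulated by the drug, with the direction reported (bioflag_sign) and the
# corroboration status the model analysis assigned under the single drug and
# under the combination. status: corroborated | antagonised | below_threshold
# | blank (protein absent from the evaluated models).
uniprot	protein	bioflag_sign	status_single	status_combo
P14902	IDO1	down	corroborated	corroborated
P08047	SP1	down	blank	blank
P02751	FN1	down	corroborated	corroborated
P19875	CXCL2	down	corroborated	corroborated
P19876	CXCL3	down	corroborated	corroborated
P25024	CXCR1	down	corroborated	corroborated
P25025	CXCR2	down	corroborated	corroborated
P32207	CXCR5	down	corroborated	corroborated
P51677	CCR3	down	corroborated	corroborated
P09919	CSF3	down	corroborated	corroborated
Q99062	CSF3R	down	corroborated	corroborated
P32927	CSF2RB	down	corroborated	corroborated
P26748	NCF1	down	corroborated	corroborated
P15153	RAC2	down	corroborated	corroborated
O60603	TLR2	down	corroborated	corroborated
Q9Y2C9	TLR6	down	corroborated	antagonised
Q9HC29	NOD2	down	corroborated	corroborated
P36222	CHI3L1	down	corroborated	corroborated
Q16552	IL17A	down	corroborated	corroborated
Q9NPF7	IL23A	down	corroborated	corroborated
Q9HBE5	IL21R	down	corroborated	corroborated
O43927	CXCL13	down	corroborated	corroborated
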