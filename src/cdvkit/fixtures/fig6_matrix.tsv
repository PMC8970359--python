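# Family-qualified domain presence/absence across the four archaeal groups,
# transcribed from the published evolutionary-scenario figure. 1 = at least one
# member of the group carries the domain on a protein of that family.
taxon	CdvA:CdvA_alpha	CdvA:CdvA_beta	CdvA:BWI	CdvA:MIM2	CdvB:Snf7	CdvB:MIM2	CdvB:BWH	CdvB:ANCHR	CdvB:MIM1	CdvC:MIT	CdvC:AAA_ATPase	CdvC:Vps4_C
Euryarchaeota	0	0	0	0	1	0	0	0	0	1	1	1
Asgard	0	0	0	0	1	1	0	1	1	1	1	1
Thaumarchaeota	1	1	0	1	1	1	0	0	0	1	1	1
Crenarchaeota	1	1	1	0	1	1	1	0	0	1	1	1
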