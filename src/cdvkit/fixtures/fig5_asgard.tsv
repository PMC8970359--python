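# Synthetic transcription of the Asgard CdvB N-terminal alignment figure:
# CdvBa1 homologs carry a proline-free predicted alpha helix (ANCHR-like)
# in the N-terminal window, CdvBa2 homologs carry a conserved helix-breaking
# proline. Sequences are synthetic stand-ins (the published alignment is an
# image); only the helix/proline structure of the figure is preserved.
protein_id	organism	clade	sequence	ss
Loki_CdvBa1	Lokiarchaeum sp. GC14_75	CdvBa1	MSDLFKKAIEATKGLAKEVRSGNLDEVLSKLGISKEDAKKVVEA	CCHHHHHHHHHHHHHHHHCCCCCCCCCCCCCCCCCCCCCCCCCC
Loki_CdvBa2	Lokiarchaeum sp. GC14_75	CdvBa2	MSDLFKKAPEATKGLAKEVRSGNLDEVLSKLGISKEDAKKVVEA	CCHHHHHCHHHHHHHHHHCCCCCCCCCCCCCCCCCCCCCCCCCC
Psyn_CdvBa1	Candidatus Prometheoarchaeum syntrophicum MK-D1	CdvBa1	MSELFKKAIDATKGLAKEVRSGNLDEVLAKLGISKEDARKVVEA	CCHHHHHHHHHHHHHHHHCCCCCCCCCCCCCCCCCCCCCCCCCC
Psyn_CdvBa2	Candidatus Prometheoarchaeum syntrophicum MK-D1	CdvBa2	MSELFKKAPDATKGLAKEVRSGNLDEVLAKLGISKEDARKVVEA	CCHHHHHCHHHHHHHHHHCCCCCCCCCCCCCCCCCCCCCCCCCC
Odin_CdvBa1	Candidatus Odinarchaeota archaeon LCB_4	CdvBa1	MADLFKKAVEATKGLAKEIRSGNLDEVLSKLGLSKEDAKKVIEA	CCHHHHHHHHHHHHHHHHCCCCCCCCCCCCCCCCCCCCCCCCCC
Odin_CdvBa2	Candidatus Odinarchaeota archaeon LCB_4	CdvBa2	MADLFKKAPEATKGLAKEIRSGNLDEVLSKLGLSKEDAKKVIEA	CCHHHHHCHHHHHHHHHHCCCCCCCCCCCCCCCCCCCCCCCCCC
Heim_CdvBa1	Candidatus Heimdallarchaeota archaeon	CdvBa1	MSDLFKRAIEATKGMAKEVRSGNLEEVLSKLGISKEDAKKVVEA	CCHHHHHHHHHHHHHHHHCCCCCCCCCCCCCCCCCCCCCCCCCC
Heim_CdvBa2	Candidatus Heimdallarchaeota archaeon	CdvBa2	MSDLFKRAPEATKGMAKEVRSGNLEEVLSKLGISKEDAKKVVEA	CCHHHHHCHHHHHHHHHHCCCCCCCCCCCCCCCCCCCCCCCCCC
ThorO_CdvBa1	Candidatus Thorarchaeota archaeon OWC	CdvBa1	MSDLFKKAIEASKGLAKEVRAGNLDEVLSKLGISREDAKKVVEA	CCHHHHHHHHHHHHHHHHCCCCCCCCCCCCCCCCCCCCCCCCCC
ThorO_CdvBa2	Candidatus Thorarchaeota archaeon OWC	CdvBa2	MSDLFKKAPEASKGLAKEVRAGNLDEVLSKLGISREDAKKVVEA	CCHHHHHCHHHHHHHHHHCCCCCCCCCCCCCCCCCCCCCCCCCC
ThorA_CdvBa1	Candidatus Thorarchaeota archaeon AB_25	CdvBa1	MSDLFKKAIEATKGLVKEVRSGNLDEVLSKLGISKEDAKRVVEA	CCHHHHHHHHHHHHHHHHCCCCCCCCCCCCCCCCCCCCCCCCCC
ThorA_CdvBa2	Candidatus Thorarchaeota archaeon AB_25	CdvBa2	MSDLFKKAPEATKGLVKEVRSGNLDEVLSKLGISKEDAKRVVEA	CCHHHHHCHHHHHHHHHHCCCCCCCCCCCCCCCCCCCCCCCCCC
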