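# illustrative functional annotation, E. coli numbering
Ecoli	2049	2051	BRIDGE
Ecoli	2057	2058	PTC,ANTIBIOTIC_RESISTANCE
Ecoli	2061	2062	A_SITE,P_SITE
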