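column_start	column_end	category	subtype	Archaea	Bacteria	Eukaryota	Ecoli	Scerevisiae	functions
1	5	UNIVERSAL	SUBSTITUTION	GCATG	GCATG	GCATG	G2046..G2050	G406..G410	BRIDGE
6	6	PAIR(Archaea,Eukaryota)	SUBSTITUTION	G	C	G	C2051	G411	BRIDGE
7	7	UNIVERSAL	SUBSTITUTION	A	A	A	A2052	A412	NONE
8	8	PAIR(Archaea,Eukaryota)	INDEL	-	Y	-	T2053	(A412)-(T413)	NONE
9	12	UNIVERSAL	SUBSTITUTION	TCGA	TCGA	TCGA	T2054..A2057	T413..A416	NONE
13	13	PAIR(Archaea,Eukaryota)	SUBSTITUTION	G	A	G	A2058	G417	ANTIBIOTIC_RESISTANCE,PTC
14	14	PAIR(Archaea,Bacteria)	INDEL	-	-	N	(A2058)-(G2059)	A418	NONE
15	15	UNIVERSAL	SUBSTITUTION	G	G	G	G2059	G419	NONE
16	16	ONLY(Eukaryota)	SUBSTITUTION	-T	R	C	A2060	C420	NONE
17	17	UNIVERSAL	SUBSTITUTION	T	T	T	T2061	T421	NONE
18	18	PAIR(Bacteria,Eukaryota)	SUBSTITUTION	G	T	T	T2062	T422	A_SITE,P_SITE
19	20	UNIVERSAL	SUBSTITUTION	AC	AC	AC	A2063..C2064	A423..C424	NONE
30	33	UNIVERSAL	SUBSTITUTION	CGTA	CGTA	CGTA	C2074..A2077	C434..A437	NONE
34	34	PAIR(Archaea,Eukaryota)	SUBSTITUTION	G	Y	R	T2078	G438	NONE
35	35	UNIVERSAL	SUBSTITUTION	C	C	C	C2079	C439	NONE
36	36	ONLY(Archaea)	SUBSTITUTION	T	M	-G	A2080	G440	NONE
37	38	PAIR(Archaea,Eukaryota)	SUBSTITUTION	BG	-Y	HR	(A2080)-(C2081)..C2081	A441..A442	NONE
39	40	UNIVERSAL	SUBSTITUTION	GC	GC	GC	G2082..C2083	G443..C444	NONE
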