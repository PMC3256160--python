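sharing	Bacteria	Ecoli	Archaea	Eukaryota	Scerevisiae
A,E	H	T340	-	-	(A412)-(T413)
A,E	Y	T358	G	G	G430
A,E	C	C507	G	D	G553
A,E	-/Y	-C514	B/G	H/R	G561
A,E	R	G537	C	Y	C584
A,E	R	G585	C	Y	T632
A,E	A	A716	C	B	C927
A,E	Y	C756	G	R	A967
A,E	G	G966	T	Y	T1191
A,E	A	A1110	G	G	G1330
B,A	-	(C1203)-(A1204)	(Y)-(A)	N	G1435
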