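# taxon	group
Ecoli	Bacteria
Bsubtilis	Bacteria
Taquaticus	Bacteria
Synechocystis	Bacteria
Mjannaschii	Archaea
Hvolcanii	Archaea
Sacidocaldarius	Archaea
Tkodakarensis	Archaea
Scerevisiae	Eukaryota
Hsapiens	Eukaryota
Athaliana	Eukaryota
Tthermophila	Eukaryota
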