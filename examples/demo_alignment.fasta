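>Ecoli
GCATGCATTCGAA-GATTACAGAACTATCCGTATCA-CGC
>Bsubtilis
GCATGCACTCGAA-GATTACCGCACTGGACGTACCA-TGC
>Taquaticus
GCATGCACTCGAA-GGTTACAGGACTCCTCGTATCC-CGC
>Synechocystis
GCATGCATTCGAA-GGTTACCGTACTTAGCGTACCC-TGC
>Mjannaschii
GCATGGA-TCGAG-GTTGACANAAGTATCCGTAGCTCGGC
>Hvolcanii
GCATGGA-TCGAG-GTTGACGNCAGTGGACGTAGCTGGGC
>Sacidocaldarius
GCATGGA-TCGAG-G-TGACAGGAGTCCTCGTAGCTTGGC
>Tkodakarensis
GCATGGA-TCGAG-G-TGACGGTAGTTAGCGTAGCTTGGC
>Scerevisiae
GCATGGA-TCGAGAGCTTACCGAAGTATCCGTAGCGAAGC
>Hsapiens
GCATGGA-TCGAGCGCTTACGGCAGTGGACGTAACGCGGC
>Athaliana
GCATGGA-TCGAGGGCTTACTGGAGTCCTCGTAGC-TAGC
>Tthermophila
GCATGGA-TCGAGTGCTTACCGTAGTTAGCGTAAC-TGGC
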