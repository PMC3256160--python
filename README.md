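# ribosig

Kingdom-signature scanning of ribosomal RNA/DNA multiple sequence
alignments.

## The problem

Ribosomal RNA is conserved enough to align across all cellular life, yet a
handful of positions carry *kingdom signatures*: states shared by every
member of two taxonomic domains and absent from the third (for instance a
base present in all archaea and all eukaryotes but in no bacterium), or
fixed in a single domain only (a synapomorphy). Such sites bear on deep
phylogeny — archaea+eukaryote signatures support an archaeal origin of the
eukaryotic ribosome — and on pharmacology, because several fall in the
peptidyl transferase centre and the tRNA binding sites, where a single
base difference (the classic A2058 of the bacterial large-subunit rRNA
versus G in eukaryotes) decides antibiotic susceptibility.

`ribosig` takes a pre-aligned rDNA matrix, a taxon→group map, and an
optional mask of variable-length regions, and finds these sites
systematically. It is written for molecular evolution researchers who
have an alignment and want a reproducible, testable replacement for
eyeballing conservation columns in an alignment editor.

## The method

For each unmasked column, the residues of each group are collected into a
symbol set over the five-letter alphabet `{A,C,G,T,-}` — the gap is a
first-class symbol, so indel signatures come out of the same algebra as
substitutions. Sequence ambiguity codes (`N`, `Y`, ...) count as missing
data, never as evidence. With per-group sets *x*, *y*, *z* a column is:

- **UNIVERSAL** — one identical non-gap symbol in every group;
- **PAIR(X,Y)** — *x* ∩ *y* ≠ ∅ and *z* ∩ (*x* ∪ *y*) = ∅: a state
  exclusively shared by X and Y (generalises to any subset of k groups
  versus its complement);
- **ONLY(X)** — |*x*| = 1 and *x* disjoint from every other group;
- **UNCLASSIFIED** otherwise,

with precedence UNIVERSAL > PAIR > ONLY. The sharing rule is deliberately
the weakest one consistent with exclusivity (X ∩ Y need not be a single
fixed base), which is what published signature tables actually contain.
Sites are mapped to reference numbering (e.g. *E. coli* 16S, *S.
cerevisiae* 18S) through an ungapped-position index with a user-set
offset; columns where the reference is gapped render as flanked loci like
`(A412)-(T413)`. A planted-signature simulator generates alignments with
known per-column categories so the whole pipeline can be validated
without downloading a single sequence.

## Worked example

Scan the shipped 12-taxon, 40-column demo alignment (three kingdoms, a
masked variable region, *E. coli* and yeast reference rows):

```sh
ribosig scan \
  --alignment examples/demo_alignment.fasta \
  --groups examples/demo_groups.tsv \
  --mask examples/demo_mask.bed \
  --ref Ecoli:2045 --ref Scerevisiae:405 \
  --annotations examples/demo_annotations.bed \
  -o demo_out
```

`demo_out/sites.tsv` contains rows like (abridged):

```text
column_start  category                 Archaea  Bacteria  Eukaryota  Ecoli          Scerevisiae    functions
8             PAIR(Archaea,Eukaryota)  -        Y         -          T2053          (A412)-(T413)  NONE
13            PAIR(Archaea,Eukaryota)  G        A         G          A2058          G417           ANTIBIOTIC_RESISTANCE,PTC
14            PAIR(Archaea,Bacteria)   -        -         N          (A2058)-(G2059) A418          NONE
37            PAIR(Archaea,Eukaryota)  BG       -Y        HR         (A2080)-(C2081)..C2081  A441..A442  NONE
```

Row one is an indel signature: archaea and eukaryotes share a deletion
(bacteria show C/T), so the yeast coordinate is the flanked locus
`(A412)-(T413)`. Row two is an A→G substitution at *E. coli* position
2058, picking up its resistance-site annotation. The last row is a merged
two-column locus whose per-group codes concatenate (`-Y` / `BG` / `HR`).
`demo_out/summary.json` adds per-category counts; the same run is frozen
as `examples/demo_sites_golden.tsv`.

Other subcommands: `ribosig synth --self-test` generates a
planted-signature dataset and scores its own recovery;
`ribosig classify-table` classifies a table of per-group consensus codes
(see `examples/ssu_signature_table.tsv`, a transcription of the published
SSU signature rows — classifying it yields 10 archaea+eukaryote rows and
1 bacteria+archaea row); `ribosig annotate` re-joins an existing site
table to a functional annotation file.

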