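# Methods

## Model and scope

`ribosig` operates on a fixed multiple sequence alignment; it does not
align. Each column is treated independently and summarised, per
taxonomic group, as the set of symbols its members exhibit over the
five-letter alphabet `{A, C, G, T, -}`. Three modelling commitments
underlie everything else:

1. **Gap is a symbol.** Published signature tables mix base signatures and
   indel signatures in one scheme; modelling the gap as a fifth residue
   lets one set algebra cover both. A signature whose diagnostic state is
   the gap is reported with subtype `INDEL`.
2. **Input ambiguity is missing data.** An `N` (or `Y`, `R`, ...) in a
   sequence record contributes nothing to its group's set. Treating a
   sequencing ambiguity as evidence for every compatible base would let a
   single low-quality record veto a true signature. Degenerate codes are
   used on *output* only, to summarise group sets.
3. **T ≡ U**; all output uses the DNA alphabet.

## Classification

With groups' observed sets (missing excluded), the category of a column
is decided with precedence UNIVERSAL > PAIR > ONLY > UNCLASSIFIED:

- **UNIVERSAL**: every group equals the same singleton non-gap set.
- **PAIR(S)** for a sharing subset S (|S| ≥ 2, complement non-empty):
  ∩<sub>S</sub> ≠ ∅ and every excluded group's set is disjoint from
  ∪<sub>S</sub>. This is the *weakest* rule consistent with exclusive
  sharing — the sharing groups need a common state, not a fixed identical
  base. The strong alternative ("identical single base in X and Y") would
  reject observed signature loci where one sharing group is internally
  variable yet still exclusively overlaps the other.
- **ONLY(X)**: X's set is a singleton disjoint from all other groups.
- **UNCLASSIFIED**: everything else, and any column in which some group
  has fewer than `min_group_fraction` (default 0.9) of its taxa observed —
  a column largely missing in one kingdom is never called a signature.

Determinism and tie-breaking. For three groups the PAIR conditions are
mutually exclusive (verified exhaustively over all 29,791 ordered triples
of non-empty symbol subsets, against an independent brute-force
restatement of the definitions). For k > 3, nested sharing subsets cannot
both qualify, but disjoint ones can; candidate subsets are tried largest
first, then lexicographically by sorted group labels. Mutually disjoint
singleton groups make ONLY ambiguous; the lexicographically first group
wins. Both tie-breaks are arbitrary but fixed.

Subtype: `INDEL` iff the gap lies in the shared intersection (PAIR) or is
the diagnostic singleton (ONLY); UNIVERSAL columns are by definition
substitution-type.

## Tolerance

`tolerance` ε (default 0, i.e. strict) allows a fraction of each group's
observed taxa to violate conservation: each group's set is recomputed
after greedily discarding the rarest symbols whose cumulative count fits
in ⌊ε·n⌋ (ties broken in fixed alphabet order; a set is never emptied).
The column is then assigned the higher-precedence of the strict and the
trimmed classification, strict winning ties. Plain trimming alone could
*destroy* a strict signature (the shared symbol may itself be rare in one
group), so taking the precedence-maximum is what guarantees the intended
monotonicity: raising ε never loses a site. Note that small groups get no
effective tolerance (⌊ε·n⌋ = 0 for n < 1/ε), which matches the intent:
with 21 archaea, one aberrant archaeon should break a strict signature.

## Coordinates

Reported positions are 1-based ungapped indices within a designated
reference row plus a user-set integer offset; file-level intervals (BED
masks, annotations) are 0-based half-open and converted only at I/O
boundaries. Published reference numbering (e.g. *E. coli* 16S) is a
convention that cannot be recovered from sequence alone — the offset is
how users reconcile a partial local reference with it. Columns gapped in
the reference render as `(A412)-(T413)` (nearest flanking bases); a gap
before the first or after the last base renders the absent side as `()`.
Reference-coordinate mask intervals that span a reference gap mask every
alignment column between the mapped flanks.

## Merging

Composite loci spanning adjacent columns (e.g. a two-column signature
whose per-group codes print as `-Y` / `BG` / `HR`) are represented
internally as single-column sites; for reports, runs of adjacent
same-category sites merge into one locus with concatenated codes
(`merge_adjacent`, default on; site-level analyses such as recovery
scoring switch it off). `classify-table` accepts multi-column cells as
`/`-separated codes and applies the same merge per row.

## Synthetic data

The generator plants columns of every category and records a truth
table. It is column-independent by design — the claims being tested
concern per-column exclusivity patterns, not phylogenetic correlation —
so no tree or substitution model is simulated. Defaults mirror the
study conditions the package is built around: group sizes 124 bacteria /
21 archaea / 362 eukaryotes, planted pair counts following the reported
census across both subunits (26 archaea+eukaryote, 6 archaea+bacteria,
1 bacteria+eukaryote, 7 eukaryote-only); universal and background column
counts are not published and are fixed once at 30 and 60.

Construction per planted column: PAIR(X,Y) draws a shared symbol (gap
for indel subtype), gives X and Y sets containing it (plus up to
`shared_extra_max` extra non-gap symbols), and gives the excluded group a
1–4 symbol set disjoint from X ∪ Y. ONLY(X) fixes X on a private symbol
and splits the remaining four symbols into two disjoint 2-symbol sets
for the other groups (additional groups, if any, straddle the split) so
that no competing PAIR or ONLY can arise. Background columns draw
uniform bases per taxon. Every sampled set is realised exactly (each
symbol forced to appear), then each cell is independently flipped to a
uniform random 5-alphabet symbol with probability `noise_rate`. One
`numpy` generator seeded by `seed` drives all randomness; identical
seeds give byte-identical datasets.

Defining guarantee (tested): at `noise_rate = 0` under strict scanning,
sensitivity and precision are exactly 1.0 for every planted category. At
the default group sizes, background columns cannot masquerade as
signatures (all four bases appear in the large groups almost surely, and
the acceptance-scale runs are seed-pinned); with very small groups
(&lt; ~8 taxa) chance exclusivity in background columns becomes possible
and would show up as a precision hit, which is the correct reading.

What the simulator does *not* emulate: phylogenetic autocorrelation,
realistic substitution processes (GTR etc.), multi-column indel length
distributions, alignment error, and secondary-structure covariation.
Passing recovery tests therefore validates the scanning logic, not the
upstream alignment quality that real analyses depend on.

## Problem sizes and reproducibility

The shipped analyses run at desk scale: the 11-row transcribed SSU
consensus table; a 12-taxon × 40-column hand-designed demo alignment
(golden output frozen in `examples/`); 507-taxon × 124-column synthetic
recovery runs (12 planted columns per category, seeds fixed); 29,791
triple evaluations for the classifier/oracle equivalence; 1,000 random
rows for coordinate round trips. `scripts/acceptance.py --seed N`
recomputes all of it in a few seconds. Reproducing the full published
census (the 26 archaea+eukaryote signatures) would require re-assembling
the original ~500-taxon GenBank samples and re-aligning after masking
variable regions; the accession lists are not machine-readable, so that
workflow is documented rather than automated.

## Known limitations

- Signature calls carry no statistical significance; the method is a
  deterministic census, and strict conservation claims are only as good
  as the taxon sampling behind the alignment.
- The variable-region masks for real rRNA must be supplied by the user
  (they are defined on rRNA secondary-structure models, not derivable
  from one alignment); the shipped masks are demonstrations.
- Functional annotations are illustrative fixtures, not a curated
  database; real analyses should supply positions from the structural
  literature.
- `min_group_fraction` interacts with heavily gapped alignment ends:
  leading/trailing incomplete sequences can push true signature columns
  into UNCLASSIFIED("insufficient data"). Trimming ragged ends or
  masking them is recommended.
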