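"""Column-conservation scanning: the kingdom-signature classifier.

Every scannable alignment column is summarised as one observed symbol set
per taxonomic group (gap included, missing data excluded) and classified:

* ``UNIVERSAL``   — all groups fixed for one identical non-gap symbol
                    (conserved across all cellular organisms);
* ``PAIR(X,Y)``   — a symbol state exclusively shared by groups X and Y:
                    their sets intersect and every other group's set is
                    disjoint from their union.  With the default three
                    kingdoms, ``PAIR(Archaea,Eukaryota)`` columns are the
                    archaea–eukaryote signatures; for k>3 groups the same
                    rule applies to any sharing subset vs. its complement;
* ``ONLY(X)``     — group X fixed for a single symbol found in no other
                    group: a synapomorphy of X;
* ``UNCLASSIFIED``— anything else, including columns with too much missing
                    data in some group.

The sharing rule is deliberately the *weakest* one consistent with
exclusivity: the excluded groups must be disjoint from the sharing groups'
union, while the sharing groups need only a non-empty intersection — not a
fixed identical base.  This admits, e.g., a column where eukaryotes show
A/G/T and archaea G while all bacteria have C.

Subtype ``INDEL`` marks signatures whose shared/diagnostic symbol is the
gap; everything else is a ``SUBSTITUTION``.

Tolerance: with ``tolerance`` ε > 0, each group's set is additionally
recomputed after greedily discarding the rarest symbols, up to ⌊ε·n⌋
observed taxa per group, and the higher-precedence of the strict and
trimmed classifications is kept.  Strict scanning therefore never loses a
site when ε is raised.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

from .coordmap import CoordinateIndex, Flank, Point, RefCoordinate
from .msaio import MISSING_CHAR, Alignment, GroupMap, RegionMask, apply_mask
from .symbols import GAP, SymbolSet, encode_iupac

SUBSTITUTION = "SUBSTITUTION"
INDEL = "INDEL"

_PRECEDENCE = {"UNIVERSAL": 3, "PAIR": 2, "ONLY": 1, "UNCLASSIFIED": 0}

# Deterministic symbol order for tie-breaking when trimming.
_SYMBOL_ORDER = {s: i for i, s in enumerate("ACGT" + GAP)}


@dataclass(frozen=True, order=False)
class Category:
    """A classification label: kind plus the groups it names (sorted)."""

    kind: str
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in _PRECEDENCE:
            raise ValueError(f"unknown category kind {self.kind!r}")
        object.__setattr__(self, "groups", tuple(sorted(self.groups)))

    @property
    def precedence(self) -> int:
        return _PRECEDENCE[self.kind]

    def __str__(self) -> str:
        if self.groups:
            return f"{self.kind}({','.join(self.groups)})"
        return self.kind


UNCLASSIFIED = Category("UNCLASSIFIED")
UNIVERSAL = Category("UNIVERSAL")


def pair(*groups: str) -> Category:
    return Category("PAIR", tuple(groups))


def only(group: str) -> Category:
    return Category("ONLY", (group,))


def parse_category(text: str) -> Category:
    """Inverse of ``str(Category)``, e.g. ``PAIR(Archaea,Eukaryota)``."""
    text = text.strip()
    if "(" in text:
        kind, rest = text.split("(", 1)
        groups = tuple(g.strip() for g in rest.rstrip(")").split(",") if g.strip())
        return Category(kind, groups)
    return Category(text)


@dataclass(frozen=True)
class ScanConfig:
    """Scanner knobs.

    min_group_fraction
        Minimum fraction of a group's taxa that must contribute a symbol
        (not missing) for the column to be classifiable at all.
    tolerance
        Fraction ε of each group's observed taxa allowed to violate strict
        conservation (0 = strict, the default).
    emit_universal
        Also report UNIVERSAL columns (they are marked in published
        secondary-structure figures, so on by default).
    merge_adjacent
        Merge runs of adjacent same-category sites into one reported locus
        (report-level behaviour; site-level analyses switch it off).
    """

    min_group_fraction: float = 0.9
    tolerance: float = 0.0
    emit_universal: bool = True
    merge_adjacent: bool = True

    def __post_init__(self) -> None:
        if not (0 < self.min_group_fraction <= 1):
            raise ValueError("min_group_fraction must be in (0, 1]")
        if not (0 <= self.tolerance < 0.5):
            raise ValueError("tolerance must be in [0, 0.5)")


@dataclass(frozen=True)
class ColumnProfile:
    """Per-group symbol tallies at one column."""

    column: int
    counts: Mapping[str, Counter]        # group -> symbol -> count
    n_observed: Mapping[str, int]
    n_missing: Mapping[str, int]
    group_sizes: Mapping[str, int]

    def observed(self, group: str) -> SymbolSet:
        return frozenset(self.counts[group])


def column_profile(aln: Alignment, gmap: GroupMap, col: int) -> ColumnProfile:
    """Tally symbols per group at ``col`` (missing data counted separately)."""
    rows = gmap.row_indices(aln)
    counts: dict[str, Counter] = {}
    n_obs: dict[str, int] = {}
    n_miss: dict[str, int] = {}
    sizes: dict[str, int] = {}
    for group, idxs in rows.items():
        c: Counter = Counter()
        miss = 0
        for i in idxs:
            ch = aln.seqs[i][col]
            if ch == MISSING_CHAR:
                miss += 1
            else:
                c[ch] += 1
        counts[group] = c
        n_obs[group] = sum(c.values())
        n_miss[group] = miss
        sizes[group] = len(idxs)
    return ColumnProfile(col, counts, n_obs, n_miss, sizes)


def _trim(counts: Counter, budget: int) -> SymbolSet:
    """Discard rarest symbols while their total count fits in ``budget``,
    never emptying the set.  Ties broken by fixed symbol order."""
    items = sorted(counts.items(), key=lambda kv: (kv[1], _SYMBOL_ORDER[kv[0]]))
    kept = dict(items)
    for sym, n in items:
        if len(kept) == 1 or n > budget:
            break
        del kept[sym]
        budget -= n
    return frozenset(kept)


def categorize_sets(sets: Mapping[str, SymbolSet]) -> tuple[Category, Optional[str]]:
    """Classify one column given the observed symbol set per group.

    Pure set logic — the heart of the method.  Precedence:
    UNIVERSAL > PAIR (larger sharing subsets first, then lexicographic)
    > ONLY (lexicographically first group) > UNCLASSIFIED.
    """
    labels = sorted(sets)
    if any(not sets[g] for g in labels):
        return UNCLASSIFIED, None
    values = [sets[g] for g in labels]
    first = values[0]
    if len(first) == 1 and GAP not in first and all(v == first for v in values):
        return UNIVERSAL, SUBSTITUTION
    k = len(labels)
    for size in range(k - 1, 1, -1):
        for subset in itertools.combinations(labels, size):
            shared = frozenset.intersection(*(sets[g] for g in subset))
            if not shared:
                continue
            union = frozenset.union(*(sets[g] for g in subset))
            rest = [g for g in labels if g not in subset]
            if all(not (sets[g] & union) for g in rest):
                subtype = INDEL if GAP in shared else SUBSTITUTION
                return Category("PAIR", subset), subtype
    for g in labels:
        s = sets[g]
        if len(s) == 1:
            others = frozenset.union(
                *(sets[h] for h in labels if h != g)
            )
            if not (s & others):
                subtype = INDEL if GAP in s else SUBSTITUTION
                return only(g), subtype
    return UNCLASSIFIED, None


def classify_profile(
    p: ColumnProfile, cfg: ScanConfig
) -> tuple[Category, Optional[str], Mapping[str, SymbolSet]]:
    """Classify a column profile; returns (category, subtype, sets used).

    Groups failing ``min_group_fraction`` (or entirely missing) make the
    column UNCLASSIFIED — a column nobody sequenced is never a signature.
    """
    for g, size in p.group_sizes.items():
        if size == 0 or p.n_observed[g] < cfg.min_group_fraction * size:
            return UNCLASSIFIED, None, {g: p.observed(g) for g in p.group_sizes}
    strict = {g: p.observed(g) for g in p.group_sizes}
    cat, subtype = categorize_sets(strict)
    sets_used: Mapping[str, SymbolSet] = strict
    if cfg.tolerance > 0:
        trimmed = {
            g: _trim(p.counts[g], int(cfg.tolerance * p.n_observed[g]))
            for g in p.group_sizes
        }
        t_cat, t_sub = categorize_sets(trimmed)
        if t_cat.precedence > cat.precedence:
            cat, subtype, sets_used = t_cat, t_sub, trimmed
    return cat, subtype, sets_used


@dataclass(frozen=True)
class SignatureSite:
    """A classified column (or merged run of columns) — one report row."""

    column: int                      # first column, 0-based
    end_column: int                  # last column, inclusive
    category: Category
    subtype: Optional[str]
    group_codes: Mapping[str, str]   # group -> IUPAC code string
    ref_coords: Mapping[str, tuple[RefCoordinate, ...]] = field(
        default_factory=dict
    )
    functions: frozenset = frozenset()

    @property
    def n_columns(self) -> int:
        return self.end_column - self.column + 1

    def rendered_coord(self, ref_name: str) -> str:
        coords = self.ref_coords[ref_name]
        if len(coords) == 1:
            return coords[0].render()
        return f"{coords[0].render()}..{coords[-1].render()}"


def scan_alignment(
    aln: Alignment,
    gmap: GroupMap,
    mask: Optional[RegionMask] = None,
    cfg: Optional[ScanConfig] = None,
    indexes: Optional[Mapping[str, CoordinateIndex]] = None,
) -> list[SignatureSite]:
    """Classify every scannable column; return classified sites in column
    order.  Deterministic; independent of record order in the alignment."""
    cfg = cfg or ScanConfig()
    indexes = indexes or {}
    gmap.validate(aln)
    sites: list[SignatureSite] = []
    for col in apply_mask(aln, mask):
        prof = column_profile(aln, gmap, col)
        cat, subtype, sets_used = classify_profile(prof, cfg)
        if cat.kind == "UNCLASSIFIED":
            continue
        if cat.kind == "UNIVERSAL" and not cfg.emit_universal:
            continue
        codes = {g: encode_iupac(s) for g, s in sets_used.items()}
        coords = {
            name: (idx.column_to_ref(col),) for name, idx in indexes.items()
        }
        sites.append(
            SignatureSite(col, col, cat, subtype, codes, coords)
        )
    return sites


def merge_adjacent_sites(sites: Sequence[SignatureSite]) -> list[SignatureSite]:
    """Merge runs of *adjacent* columns with identical category into one
    locus; per-group codes concatenate (two adjacent gap-or-base columns
    print like ``-Y``), coordinates keep the first and last column's."""
    merged: list[SignatureSite] = []
    for site in sorted(sites, key=lambda s: s.column):
        if (
            merged
            and site.column == merged[-1].end_column + 1
            and site.category == merged[-1].category
        ):
            prev = merged[-1]
            merged[-1] = replace(
                prev,
                end_column=site.end_column,
                subtype=INDEL if INDEL in (prev.subtype, site.subtype)
                else prev.subtype,
                group_codes={
                    g: prev.group_codes[g] + site.group_codes[g]
                    for g in prev.group_codes
                },
                ref_coords={
                    name: prev.ref_coords[name] + site.ref_coords[name]
                    for name in prev.ref_coords
                },
                functions=prev.functions | site.functions,
            )
        else:
            merged.append(site)
    return merged


def summarize_categories(sites: Sequence[SignatureSite]) -> dict[str, int]:
    """Per-category site counts (stringified categories, sorted keys)."""
    out: Counter = Counter(str(s.category) for s in sites)
    return dict(sorted(out.items()))
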