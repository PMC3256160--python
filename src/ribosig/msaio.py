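"""Alignment, group-map and region-mask I/O.

File conventions
----------------
* aligned FASTA in/out (residues normalised on read: case-folded, U→T,
  ``.``→``-``, ambiguity characters collapsed to ``N`` = missing);
* taxon→group map as two-column TSV (``taxon<TAB>group``);
* masks and annotations as BED-like three/four-column TSV, 0-based
  half-open; reported coordinates elsewhere are 1-based — the conversion
  happens only at these I/O boundaries.

All readers tolerate CRLF line endings and ``#`` comment lines.

The pipeline consumes a *pre-aligned* matrix: computing the alignment
(e.g. with MUSCLE or MAFFT after excising variable-length regions) is an
external step.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .symbols import GAP

#: Internal matrix alphabet: the five symbols plus ``N`` for missing data.
MISSING_CHAR = "N"
_NON_SYMBOL = re.compile(r"[^ACGT\-]")


def normalize_sequence(raw: str) -> str:
    """Normalise a residue string to the internal ``ACGT-N`` alphabet."""
    s = raw.upper().replace("U", "T").replace(".", GAP)
    return _NON_SYMBOL.sub(MISSING_CHAR, s)


@dataclass(frozen=True)
class Alignment:
    """An immutable aligned matrix of normalised residue strings.

    Invariants: all rows share one width; taxon identifiers are unique.
    """

    ids: tuple[str, ...]
    seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ids:
            raise ValueError("alignment has no records")
        if len(self.ids) != len(self.seqs):
            raise ValueError("ids and seqs length mismatch")
        widths = {len(s) for s in self.seqs}
        if len(widths) != 1:
            ragged = [
                t for t, s in zip(self.ids, self.seqs)
                if len(s) != len(self.seqs[0])
            ]
            raise ValueError(f"ragged alignment; offending taxa: {ragged}")
        seen: set[str] = set()
        dups = [t for t in self.ids if t in seen or seen.add(t)]
        if dups:
            raise ValueError(f"duplicate taxon identifiers: {sorted(set(dups))}")

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str]]) -> "Alignment":
        pairs = [(t, normalize_sequence(s)) for t, s in records]
        return cls(tuple(t for t, _ in pairs), tuple(s for _, s in pairs))

    @property
    def width(self) -> int:
        return len(self.seqs[0])

    @property
    def n_taxa(self) -> int:
        return len(self.ids)

    def row(self, taxon: str) -> str:
        try:
            return self.seqs[self.ids.index(taxon)]
        except ValueError:
            raise KeyError(f"taxon {taxon!r} not in alignment") from None

    def column(self, col: int) -> str:
        return "".join(s[col] for s in self.seqs)


def read_alignment(path) -> Alignment:
    """Read an aligned FASTA file into a normalised :class:`Alignment`."""
    records = [(r.id, str(r.seq)) for r in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return Alignment.from_records(records)


def write_alignment(aln: Alignment, path) -> None:
    recs = [
        SeqRecord(Seq(s), id=t, description="")
        for t, s in zip(aln.ids, aln.seqs)
    ]
    SeqIO.write(recs, str(path), "fasta")


def _data_lines(path) -> Iterable[tuple[int, str]]:
    text = Path(path).read_text()
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.rstrip("\r\n").rstrip()
        if not line or line.startswith("#"):
            continue
        yield lineno, line


@dataclass(frozen=True)
class GroupMap:
    """Assignment of every taxon to exactly one taxonomic group."""

    assignments: Mapping[str, str]

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.assignments.values())))

    def members(self, group: str) -> tuple[str, ...]:
        return tuple(t for t, g in self.assignments.items() if g == group)

    def validate(self, aln: Alignment, min_group_size: int = 1) -> None:
        """Check coverage of an alignment; raise on unassigned taxa,
        fewer than two groups, or undersized groups."""
        missing = [t for t in aln.ids if t not in self.assignments]
        if missing:
            raise ValueError(f"taxa absent from group map: {missing}")
        counts: dict[str, int] = {}
        for t in aln.ids:
            g = self.assignments[t]
            counts[g] = counts.get(g, 0) + 1
        if len(counts) < 2:
            raise ValueError("group map must cover at least 2 distinct groups")
        small = {g: n for g, n in counts.items() if n < min_group_size}
        if small:
            raise ValueError(
                f"groups below minimum size {min_group_size}: {small}"
            )

    def row_indices(self, aln: Alignment) -> dict[str, list[int]]:
        """Alignment row indices per group, for groups present in ``aln``."""
        out: dict[str, list[int]] = {}
        for i, t in enumerate(aln.ids):
            out.setdefault(self.assignments[t], []).append(i)
        return {g: out[g] for g in sorted(out)}


def read_group_map(path) -> GroupMap:
    """Read a two-column ``taxon<TAB>group`` TSV."""
    assignments: dict[str, str] = {}
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise ValueError(f"{path}:{lineno}: expected 'taxon<TAB>group'")
        taxon, group = parts[0], parts[1]
        if taxon in assignments and assignments[taxon] != group:
            raise ValueError(
                f"{path}:{lineno}: taxon {taxon!r} listed with conflicting "
                f"groups {assignments[taxon]!r} and {group!r}"
            )
        assignments[taxon] = group
    if not assignments:
        raise ValueError(f"empty group map: {path}")
    return GroupMap(assignments)


def write_group_map(gmap: GroupMap, path) -> None:
    with open(path, "w") as fh:
        for taxon, group in gmap.assignments.items():
            fh.write(f"{taxon}\t{group}\n")


@dataclass(frozen=True)
class RegionMask:
    """A set of alignment columns excluded from scanning.

    Stored normalised: merged, in-bounds column indices.  Variable-length
    rRNA regions that defeat alignment are the canonical thing to mask.
    """

    columns: frozenset = field(default_factory=frozenset)

    @classmethod
    def from_intervals(cls, intervals: Sequence[tuple[int, int]]) -> "RegionMask":
        cols: set[int] = set()
        for start, end in intervals:
            if start < 0 or start >= end:
                raise ValueError(f"invalid interval [{start}, {end})")
            cols.update(range(start, end))
        return cls(frozenset(cols))

    def __or__(self, other: "RegionMask") -> "RegionMask":
        return RegionMask(self.columns | other.columns)


def read_mask(path, index=None) -> RegionMask:
    """Read a BED-like mask (``name  start  end``, 0-based half-open).

    Lines whose name equals ``index.ref_taxon`` (when a
    :class:`~ribosig.coordmap.CoordinateIndex` is supplied) are interpreted
    as *reference-coordinate* intervals and lifted to alignment columns:
    the lifted range runs from the column of the first reference base to
    the column of the last, so alignment columns inserted between reference
    bases (reference gaps) are masked too.  All other lines are plain
    alignment-column intervals.
    """
    col_intervals: list[tuple[int, int]] = []
    cols: set[int] = set()
    for lineno, line in _data_lines(path):
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{lineno}: expected 'name start end'")
        name = parts[0]
        try:
            start, end = int(parts[1]), int(parts[2])
        except ValueError:
            raise ValueError(f"{path}:{lineno}: non-integer coordinates") from None
        if start < 0 or start >= end:
            raise ValueError(f"{path}:{lineno}: invalid interval [{start}, {end})")
        if index is not None and name == index.ref_taxon:
            # BED start s / end e cover reference positions s+1 .. e
            # (1-based, in the index's reported numbering).
            left = index.ref_to_column(start + 1)
            right = index.ref_to_column(end)
            cols.update(range(left, right + 1))
        else:
            col_intervals.append((start, end))
    mask = RegionMask.from_intervals(col_intervals)
    return RegionMask(mask.columns | cols)


def write_mask(mask: RegionMask, path, name: str = "mask") -> None:
    """Write the mask back out as merged BED intervals."""
    cols = sorted(mask.columns)
    with open(path, "w") as fh:
        i = 0
        while i < len(cols):
            j = i
            while j + 1 < len(cols) and cols[j + 1] == cols[j] + 1:
                j += 1
            fh.write(f"{name}\t{cols[i]}\t{cols[j] + 1}\n")
            i = j + 1


def apply_mask(aln: Alignment, mask: RegionMask | None) -> tuple[int, ...]:
    """Scannable column indices: ``{0..width-1}`` minus the masked columns.

    The alignment is never mutated; out-of-bounds masked columns raise.
    """
    if mask is None:
        return tuple(range(aln.width))
    out_of_bounds = [c for c in mask.columns if c < 0 or c >= aln.width]
    if out_of_bounds:
        raise ValueError(
            f"masked columns outside alignment width {aln.width}: "
            f"{sorted(out_of_bounds)[:5]}"
        )
    return tuple(c for c in range(aln.width) if c not in mask.columns)
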