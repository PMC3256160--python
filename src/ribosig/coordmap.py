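"""Alignment-column ↔ ungapped-reference coordinate mapping.

Signature sites are conventionally reported in the residue numbering of a
reference organism (E. coli for 16S/23S, S. cerevisiae for 18S/25S).  That
numbering cannot be derived from sequence alone, so reported position =
ungapped index within the supplied reference row + a user-set *offset* that
reconciles the local reference with the published numbering.

A column where the reference row has a gap maps to a *flanked-gap* locus,
rendered ``(A412)-(T413)``: the nearest reference bases on either side.
Positions in this module's public API are 1-based (report convention);
alignment columns are 0-based.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np

from .msaio import Alignment
from .symbols import GAP


@dataclass(frozen=True)
class Point:
    """A reference base: character + reported (offset-applied) position."""

    base: str
    position: int

    def render(self) -> str:
        return f"{self.base}{self.position}"


@dataclass(frozen=True)
class Flank:
    """A locus between two reference bases (the reference is gapped here).

    A ``None`` side means the gap is before the first / after the last
    reference base; it renders as ``()``.
    """

    left: Optional[Point]
    right: Optional[Point]

    def render(self) -> str:
        l = f"({self.left.render()})" if self.left else "()"
        r = f"({self.right.render()})" if self.right else "()"
        return f"{l}-{r}"


RefCoordinate = Union[Point, Flank]

_POINT_RE = re.compile(r"^([A-Za-z])(\d+)$")
_FLANK_RE = re.compile(
    r"^\(\s*(?:([A-Za-z])(\d+))?\s*\)\s*-\s*\(\s*(?:([A-Za-z])(\d+))?\s*\)$"
)


def parse_ref_coordinate(text: str) -> RefCoordinate:
    """Parse a rendered coordinate (``G561`` or ``(A412) - (T413)``).

    Whitespace-insensitive on the flank form.
    """
    t = text.strip()
    m = _POINT_RE.match(t)
    if m:
        return Point(m.group(1).upper(), int(m.group(2)))
    m = _FLANK_RE.match(t)
    if m:
        lb, lp, rb, rp = m.groups()
        left = Point(lb.upper(), int(lp)) if lb else None
        right = Point(rb.upper(), int(rp)) if rb else None
        return Flank(left, right)
    raise ValueError(f"unparseable reference coordinate: {text!r}")


class CoordinateIndex:
    """Bidirectional column↔position maps for one reference row.

    ``col_to_pos[c]`` = number of reference bases at columns ``<= c``
    (0 before the first base); adding ``offset`` gives the reported
    position.  ``pos_to_col[p]`` (1-based, offset removed) is the unique
    column carrying reference base ``p``.
    """

    def __init__(self, ref_taxon: str, ref_row: str, offset: int = 0):
        self.ref_taxon = ref_taxon
        self.ref_row = ref_row
        self.offset = offset
        is_base = np.frombuffer(ref_row.encode(), dtype="S1") != GAP.encode()
        self.col_to_pos = np.cumsum(is_base)
        n = int(self.col_to_pos[-1]) if len(ref_row) else 0
        if n == 0:
            raise ValueError(
                f"reference {ref_taxon!r} contains no bases (all-gap row)"
            )
        self.n_bases = n
        pos_to_col = np.zeros(n + 1, dtype=np.int64)
        pos_to_col[self.col_to_pos[is_base]] = np.nonzero(is_base)[0]
        self.pos_to_col = pos_to_col

    def column_to_ref(self, col: int) -> RefCoordinate:
        """Map an alignment column to a point or flanked-gap coordinate."""
        if col < 0 or col >= len(self.ref_row):
            raise IndexError(f"column {col} outside width {len(self.ref_row)}")
        if self.ref_row[col] != GAP:
            pos = int(self.col_to_pos[col])
            return Point(self.ref_row[col], pos + self.offset)
        left_pos = int(self.col_to_pos[col])  # bases up to the gap
        left = None
        if left_pos >= 1:
            lcol = int(self.pos_to_col[left_pos])
            left = Point(self.ref_row[lcol], left_pos + self.offset)
        right = None
        if left_pos + 1 <= self.n_bases:
            rcol = int(self.pos_to_col[left_pos + 1])
            right = Point(self.ref_row[rcol], left_pos + 1 + self.offset)
        return Flank(left, right)

    def ref_to_column(self, pos: int) -> int:
        """Map a reported 1-based reference position to its column."""
        p = pos - self.offset
        if p < 1 or p > self.n_bases:
            raise ValueError(
                f"position {pos} outside reference {self.ref_taxon!r} "
                f"(valid: {1 + self.offset}..{self.n_bases + self.offset})"
            )
        return int(self.pos_to_col[p])


def build_index(aln: Alignment, ref_taxon: str, offset: int = 0) -> CoordinateIndex:
    """Build a :class:`CoordinateIndex` from one alignment row."""
    return CoordinateIndex(ref_taxon, aln.row(ref_taxon), offset)
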